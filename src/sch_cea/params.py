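"""Shared parameter containers for the cost-effectiveness pipeline.

The five intervention arms of the Symptom Care at Home (SCH) component trial
are modelled as independent strategies.  Each strategy is described by

* weekly unplanned-utilization parameters (:class:`UtilizationParams`),
* a weekly symptom-burden trajectory (:class:`SymptomTrajectory`), and
* intervention / unit costs (:class:`CostInputs`),

which together feed a 26-week, 1-week-cycle Markov cohort model.  Costs are
expressed in 2023 US dollars and probabilities as per-week fractions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "Arm",
    "Moments",
    "UtilizationParams",
    "SymptomTrajectory",
    "DistParams",
    "CostInputs",
    "ModelConfig",
    "StrategyOutcome",
    "TABLE_UTILIZATION",
    "TABLE_EFFECT_SCORES",
    "default_utilization",
    "default_cost_inputs",
]


class Arm(str, Enum):
    """The five ePRO intervention strategies.

    SCC
        automated self-management coaching alone
    SCC_AT
        coaching plus a participant-visible activity tracker
    NP
        nurse-practitioner follow-up only
    NP_DSS
        NP follow-up with guideline-based decision support
    COMPLETE_SCH
        coaching + activity tracker + NP follow-up with decision support
    """

    SCC = "SCC"
    SCC_AT = "SCC_AT"
    NP = "NP"
    NP_DSS = "NP_DSS"
    COMPLETE_SCH = "COMPLETE_SCH"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class Moments:
    """A (mean, sd) summary of an input parameter."""

    mean: float
    sd: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.mean):
            raise ValueError(f"mean must be finite, got {self.mean}")
        if not (self.sd >= 0):
            raise ValueError(f"sd must be >= 0, got {self.sd}")


@dataclass(frozen=True)
class UtilizationParams:
    """Weekly unplanned-utilization inputs for one arm.

    ``p_ed_week`` / ``p_hosp_week`` are the per-week probabilities of having
    any ED visit / unplanned hospitalization; their SDs are across-patient
    SDs of per-patient weekly proportions.  ``n_ed_given_any`` /
    ``n_hosp_given_any`` are expected visit multiplicities in a week with at
    least one event (support on [1, inf)).  ``los_days`` is the mean length
    of stay per hospitalization, in nights.  Conditional fields are ``None``
    ("missing") when no event of that type was observed.
    """

    arm: Arm
    p_ed_week: Moments
    n_ed_given_any: Optional[Moments]
    p_hosp_week: Moments
    n_hosp_given_any: Optional[Moments]
    los_days: Optional[Moments]

    def __post_init__(self) -> None:
        for name in ("p_ed_week", "p_hosp_week"):
            m = getattr(self, name)
            if not 0.0 <= m.mean <= 1.0:
                raise ValueError(f"{name}.mean must lie in [0, 1], got {m.mean}")
        for name in ("n_ed_given_any", "n_hosp_given_any"):
            m = getattr(self, name)
            if m is not None and m.mean < 1.0:
                raise ValueError(f"{name}.mean must be >= 1, got {m.mean}")
        if self.los_days is not None and not self.los_days.mean > 0:
            raise ValueError(f"los_days.mean must be > 0, got {self.los_days.mean}")


@dataclass(frozen=True)
class SymptomTrajectory:
    """Weekly mean symptom-burden scores for one arm and their summary.

    ``weekly_scores`` holds up to 26 weekly means on the 0-10 burden scale
    (NaN marks weeks with no reported days).  ``quad_coeffs`` are the
    least-squares coefficients (a, b, c) of S(t) = a + b t + c t^2 fitted to
    the weekly series, and ``effect_score`` is the horizon-mean burden
    (1/T) * integral of S over [0, T] — the model's effectiveness measure,
    lower is better.
    """

    arm: Arm
    weekly_scores: tuple
    quad_coeffs: Optional[tuple] = None
    effect_score: Optional[float] = None

    def __post_init__(self) -> None:
        scores = tuple(float(s) for s in self.weekly_scores)
        object.__setattr__(self, "weekly_scores", scores)
        if len(scores) != 26:
            raise ValueError(
                f"weekly_scores must have length 26, got {len(scores)}"
            )
        for s in scores:
            if not math.isnan(s) and not 0.0 <= s <= 10.0:
                raise ValueError(f"weekly score {s} outside [0, 10]")
        if self.effect_score is not None and not 0.0 <= self.effect_score <= 10.0:
            raise ValueError(
                f"effect_score must lie in [0, 10], got {self.effect_score}"
            )

    @property
    def n_missing(self) -> int:
        return sum(1 for s in self.weekly_scores if math.isnan(s))


@dataclass(frozen=True)
class DistParams:
    """A beta or gamma distribution parameterized by method of moments.

    ``kind`` is ``"beta"`` (args = (alpha, beta)) or ``"gamma"``
    (args = (shape, scale)).  A source sd of exactly 0 yields a degenerate
    point mass at the mean (args empty).  ``source_mean`` / ``source_sd``
    record the moments the parameters were derived from.
    """

    kind: str
    args: tuple
    source_mean: float
    source_sd: float

    def __post_init__(self) -> None:
        if self.kind not in ("beta", "gamma"):
            raise ValueError(f"kind must be 'beta' or 'gamma', got {self.kind!r}")
        if any(a <= 0 for a in self.args):
            raise ValueError(f"distribution parameters must be > 0, got {self.args}")

    @property
    def degenerate(self) -> bool:
        return not self.args

    def analytic_mean(self) -> float:
        if self.degenerate:
            return self.source_mean
        if self.kind == "beta":
            a, b = self.args
            return a / (a + b)
        shape, scale = self.args
        return shape * scale

    def analytic_var(self) -> float:
        if self.degenerate:
            return 0.0
        if self.kind == "beta":
            a, b = self.args
            return a * b / ((a + b) ** 2 * (a + b + 1.0))
        shape, scale = self.args
        return shape * scale**2

    def sample(self, rng: np.random.Generator, size=None) -> np.ndarray:
        """Draw from the distribution (point mass when degenerate)."""
        if self.degenerate:
            return np.full(size if size is not None else (), self.source_mean)
        if self.kind == "beta":
            return rng.beta(self.args[0], self.args[1], size=size)
        return rng.gamma(self.args[0], self.args[1], size=size)


# --- printed model inputs -------------------------------------------------
# Weekly utilization inputs per arm: probabilities as fractions, conditional
# visit multiplicities, and LOS in nights, each as (mean, sd).
TABLE_UTILIZATION = {
    Arm.SCC: dict(
        p_ed_week=(0.037, 0.079), n_ed_given_any=(1.6, 0.8),
        p_hosp_week=(0.034, 0.089), n_hosp_given_any=(1.3, 0.4),
        los_days=(4.7, 4.2),
    ),
    Arm.SCC_AT: dict(
        p_ed_week=(0.042, 0.108), n_ed_given_any=(2.0, 1.8),
        p_hosp_week=(0.025, 0.069), n_hosp_given_any=(1.3, 0.7),
        los_days=(5.0, 4.6),
    ),
    Arm.NP: dict(
        p_ed_week=(0.044, 0.098), n_ed_given_any=(1.7, 1.0),
        p_hosp_week=(0.030, 0.094), n_hosp_given_any=(1.4, 0.6),
        los_days=(5.2, 3.4),
    ),
    Arm.NP_DSS: dict(
        p_ed_week=(0.031, 0.066), n_ed_given_any=(2.1, 2.9),
        p_hosp_week=(0.020, 0.053), n_hosp_given_any=(1.7, 1.9),
        los_days=(3.6, 2.2),
    ),
    Arm.COMPLETE_SCH: dict(
        p_ed_week=(0.047, 0.144), n_ed_given_any=(1.7, 1.8),
        p_hosp_week=(0.027, 0.085), n_hosp_given_any=(1.3, 0.6),
        los_days=(4.7, 4.4),
    ),
}

# Published base-case 26-week mean burden scores (0-10 scale, lower better).
TABLE_EFFECT_SCORES = {
    Arm.SCC: 6.5,
    Arm.SCC_AT: 6.9,
    Arm.NP: 5.2,
    Arm.NP_DSS: 5.3,
    Arm.COMPLETE_SCH: 4.5,
}

# Published arm sizes (the ones accompanying the utilization inputs).
TABLE_ARM_SIZES = {
    Arm.SCC: 143,
    Arm.SCC_AT: 147,
    Arm.NP: 150,
    Arm.NP_DSS: 157,
    Arm.COMPLETE_SCH: 171,
}


def default_utilization(arm: Arm) -> UtilizationParams:
    """Published weekly-utilization inputs for ``arm``."""
    row = TABLE_UTILIZATION[arm]
    return UtilizationParams(
        arm=arm,
        p_ed_week=Moments(*row["p_ed_week"]),
        n_ed_given_any=Moments(*row["n_ed_given_any"]),
        p_hosp_week=Moments(*row["p_hosp_week"]),
        n_hosp_given_any=Moments(*row["n_hosp_given_any"]),
        los_days=Moments(*row["los_days"]),
    )


@dataclass(frozen=True)
class CostInputs:
    """Unit and intervention costs, 2023 USD.

    ``dev_per_patient`` is the per-patient share of the system development
    cost (the uniform development component embedded in every per-patient
    intervention cost); ``dev_total`` is carried as metadata.  The map
    ``intervention_cost_per_patient`` holds the published per-patient
    intervention totals including the development share.
    """

    c_ed_visit: Moments = Moments(1135.0, 33.0)
    c_night: Moments = Moments(3574.0, 122.0)
    dev_total: float = 491_118.0
    dev_per_patient: float = 1253.0
    np_wage: float = 59.80
    np_hours_dss: float = 19.79
    np_hours_nondss: float = 11.46
    intervention_cost_per_patient: dict = field(
        default_factory=lambda: {
            Arm.SCC: 1253.0,
            Arm.SCC_AT: 1253.0,
            Arm.NP: 1309.0,
            Arm.NP_DSS: 1343.0,
            Arm.COMPLETE_SCH: 1340.0,
        }
    )

    def __post_init__(self) -> None:
        for name in ("dev_total", "dev_per_patient", "np_wage",
                     "np_hours_dss", "np_hours_nondss"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for arm, cost in self.intervention_cost_per_patient.items():
            if cost < self.dev_per_patient:
                raise ValueError(
                    f"intervention cost for {arm} ({cost}) below the "
                    f"development share ({self.dev_per_patient})"
                )

    def labor_component(self, arm: Arm) -> float:
        """Arm-specific intervention cost net of the development share."""
        return self.intervention_cost_per_patient[Arm(arm)] - self.dev_per_patient


def default_cost_inputs() -> CostInputs:
    return CostInputs()


@dataclass(frozen=True)
class ModelConfig:
    """Run configuration for the Markov cohort model and PSA.

    ``horizon_weeks`` = cycles (1 week each); ``cohort_size`` = simulated
    patients in the microsimulation; ``psa_outer`` (K) second-order draws and
    ``psa_inner`` (M) first-order patients per draw; ``wtp_grid`` =
    willingness-to-pay thresholds in dollars per 1-point burden reduction.
    A seed is mandatory: every stochastic stage must be reproducible.
    """

    seed: int
    horizon_weeks: int = 26
    cohort_size: int = 10_000
    include_development: bool = True
    include_visit_multiplier: bool = True
    psa_outer: int = 1000
    psa_inner: int = 1000
    wtp_grid: tuple = tuple(float(x) for x in range(0, 20_001, 250))

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is required (reproducibility contract)")
        if self.horizon_weeks < 1:
            raise ValueError("horizon_weeks must be >= 1")
        if self.cohort_size < 1:
            raise ValueError("cohort_size must be >= 1")
        if self.psa_outer < 1 or self.psa_inner < 1:
            raise ValueError("psa_outer and psa_inner must be >= 1")
        grid = tuple(float(w) for w in self.wtp_grid)
        object.__setattr__(self, "wtp_grid", grid)
        if any(w < 0 for w in grid):
            raise ValueError("wtp_grid values must be >= 0")

    def with_(self, **kwargs) -> "ModelConfig":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class StrategyOutcome:
    """Per-arm 26-week expected cost and effectiveness.

    ``total_cost`` is dollars per patient over the horizon; ``effect_score``
    the horizon-mean burden (lower better); ``mc_se_cost`` the Monte Carlo
    standard error of the cost (0 for the closed form).
    """

    arm: Arm
    total_cost: float
    effect_score: float
    mc_se_cost: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.effect_score <= 10.0:
            raise ValueError(
                f"effect_score must lie in [0, 10], got {self.effect_score}"
            )
        if self.mc_se_cost < 0:
            raise ValueError("mc_se_cost must be >= 0")
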