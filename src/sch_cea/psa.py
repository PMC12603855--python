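"""Second-order probabilistic sensitivity analysis and acceptability curves.

Each outer draw samples every uncertain model input simultaneously —
weekly event probabilities from beta distributions, unit costs, conditional
visit multiplicities (shifted: 1 + gamma on the excess) and lengths of stay
from gamma distributions — and re-runs the cohort model.  Burden scores are
held constant across draws (no individual-level variability was available
to parameterize them), so uncertainty propagates through costs only.
Intervention and development costs are fixed (no dispersion is published
for them); a config toggle is not needed since their DistParams would be
degenerate anyway.

Acceptability at willingness-to-pay λ is the fraction of draws in which a
strategy attains the maximal net monetary benefit
NMB = λ·(10 − burden) − cost (ties split equally).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd

from .calibrate import beta_from_moments, gamma_from_moments, intervention_cost
from .params import (
    Arm,
    CostInputs,
    DistParams,
    Moments,
    ModelConfig,
    StrategyOutcome,
    SymptomTrajectory,
    UtilizationParams,
)
from .markov import expected_weekly_cost, run_cohort_simulation

__all__ = [
    "EFFECT_ANCHOR",
    "ArmDists",
    "PSAResult",
    "CEACCurve",
    "build_arm_dists",
    "draw_psa_inputs",
    "run_psa",
    "nmb",
    "ceac",
]

EFFECT_ANCHOR = 10.0


@dataclass(frozen=True)
class ArmDists:
    """Sampling distributions for one arm's uncertain utilization inputs."""

    arm: Arm
    p_ed: DistParams
    n_ed_excess: Optional[DistParams]   # gamma on (count - 1)
    p_hosp: DistParams
    n_hosp_excess: Optional[DistParams]
    los: Optional[DistParams]


def _excess_count_dist(m: Optional[Moments]) -> Optional[DistParams]:
    if m is None:
        return None
    excess = m.mean - 1.0
    if excess <= 0 or m.sd == 0:
        # no excess over one visit, or no dispersion: point mass
        return DistParams("gamma", (), max(excess, 0.0), 0.0)
    return gamma_from_moments(excess, m.sd)


def _probability_dist(m: Moments) -> DistParams:
    if m.mean <= 0.0 or m.mean >= 1.0:
        # boundary probability (e.g. no events observed): point mass
        return DistParams("beta", (), m.mean, 0.0)
    return beta_from_moments(m.mean, m.sd)


def build_arm_dists(u: UtilizationParams) -> ArmDists:
    """Beta/gamma distributions for an arm's utilization parameters."""
    return ArmDists(
        arm=u.arm,
        p_ed=_probability_dist(u.p_ed_week),
        n_ed_excess=_excess_count_dist(u.n_ed_given_any),
        p_hosp=_probability_dist(u.p_hosp_week),
        n_hosp_excess=_excess_count_dist(u.n_hosp_given_any),
        los=(gamma_from_moments(u.los_days.mean, u.los_days.sd)
             if u.los_days is not None else None),
    )


def draw_psa_inputs(
    dists: Dict[Arm, ArmDists],
    cost_inputs: CostInputs,
    seed: int,
    size: int = 1,
) -> tuple:
    """Sample ``size`` joint parameter realizations.

    Returns ``(util_draws, cost_draws)`` where ``util_draws[arm]`` is a dict
    of arrays ``p_ed, n_ed, p_hosp, n_hosp, los`` of length ``size`` and
    ``cost_draws`` has arrays ``c_ed_visit, c_night`` (shared across arms —
    the unit costs are common inputs).  All draws are independent;
    ``seed`` is mandatory.
    """
    if seed is None:
        raise ValueError("seed is required (reproducibility contract)")
    rng = np.random.default_rng(seed)

    def _gamma(m: Moments) -> np.ndarray:
        return gamma_from_moments(m.mean, m.sd).sample(rng, size)

    cost_draws = {
        "c_ed_visit": _gamma(cost_inputs.c_ed_visit),
        "c_night": _gamma(cost_inputs.c_night),
    }
    util_draws = {}
    for arm in Arm:
        if arm not in dists:
            continue
        d = dists[arm]
        util_draws[arm] = {
            "p_ed": d.p_ed.sample(rng, size),
            "n_ed": (1.0 + d.n_ed_excess.sample(rng, size)
                     if d.n_ed_excess is not None else np.ones(size)),
            "p_hosp": d.p_hosp.sample(rng, size),
            "n_hosp": (1.0 + d.n_hosp_excess.sample(rng, size)
                       if d.n_hosp_excess is not None else np.ones(size)),
            "los": (d.los.sample(rng, size) if d.los is not None
                    else np.zeros(size)),
        }
    return util_draws, cost_draws


@dataclass(frozen=True)
class PSAResult:
    """Per-draw costs (K x arms) with fixed effects, plus run identity."""

    arms: tuple
    costs: np.ndarray          # shape (K, n_arms)
    effects: np.ndarray        # shape (n_arms,), constant across draws
    seed: int
    config_hash: str

    @property
    def n_draws(self) -> int:
        return self.costs.shape[0]

    def mean_outcomes(self) -> list:
        """Per-arm PSA mean cost (with MC SE) and the fixed effect."""
        out = []
        K = self.n_draws
        for j, arm in enumerate(self.arms):
            col = self.costs[:, j]
            se = float(np.std(col, ddof=1) / np.sqrt(K)) if K > 1 else 0.0
            out.append(StrategyOutcome(
                arm=arm, total_cost=float(col.mean()),
                effect_score=float(self.effects[j]), mc_se_cost=se,
            ))
        return out

    def to_frame(self) -> pd.DataFrame:
        """Long-format per-draw table: draw, arm, cost, effect."""
        K, A = self.costs.shape
        return pd.DataFrame({
            "draw": np.repeat(np.arange(K), A),
            "arm": [a.value for a in self.arms] * K,
            "cost": self.costs.ravel(),
            "effect": np.tile(self.effects, K),
        })


def _config_hash(config: ModelConfig) -> str:
    payload = {k: getattr(config, k) for k in (
        "seed", "horizon_weeks", "cohort_size", "include_development",
        "include_visit_multiplier", "psa_outer", "psa_inner", "wtp_grid",
    )}
    blob = json.dumps(payload, sort_keys=True, default=list)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_psa(
    calibration: dict,
    cost_inputs: CostInputs,
    config: ModelConfig,
    microsim_inner: bool = False,
) -> PSAResult:
    """K-outer-draw PSA over all calibrated arms.

    ``calibration`` maps arm -> (UtilizationParams, SymptomTrajectory).
    The inner evaluation is the closed-form expectation by default;
    ``microsim_inner=True`` instead simulates ``config.psa_inner``
    hypothetical patients per draw (first-order noise around the same mean).
    """
    arms = [a for a in Arm if a in calibration]
    if not arms:
        raise ValueError("calibration is empty")
    K = config.psa_outer
    dists = {a: build_arm_dists(calibration[a][0]) for a in arms}
    util_draws, cost_draws = draw_psa_inputs(
        dists, cost_inputs, seed=config.seed, size=K)

    effects = np.array(
        [calibration[a][1].effect_score for a in arms], dtype=float)
    if np.isnan(effects).any():
        raise ValueError("all arms need a calibrated effect score")

    costs = np.empty((K, len(arms)))
    inner_seeds = (np.random.SeedSequence(config.seed).spawn(K * len(arms))
                   if microsim_inner else None)
    for j, arm in enumerate(arms):
        d = util_draws[arm]
        base_interv = intervention_cost(
            arm, cost_inputs, include_development=config.include_development)
        if not microsim_inner:
            n_ed = d["n_ed"] if config.include_visit_multiplier else 1.0
            n_hosp = d["n_hosp"] if config.include_visit_multiplier else 1.0
            weekly = (d["p_ed"] * n_ed * cost_draws["c_ed_visit"]
                      + d["p_hosp"] * n_hosp * cost_draws["c_night"] * d["los"])
            costs[:, j] = config.horizon_weeks * weekly + base_interv
        else:
            traj = calibration[arm][1]
            for k in range(K):
                u_k = UtilizationParams(
                    arm=arm,
                    p_ed_week=Moments(float(d["p_ed"][k]), 0.0),
                    n_ed_given_any=Moments(max(float(d["n_ed"][k]), 1.0), 0.0),
                    p_hosp_week=Moments(float(d["p_hosp"][k]), 0.0),
                    n_hosp_given_any=Moments(max(float(d["n_hosp"][k]), 1.0), 0.0),
                    los_days=Moments(max(float(d["los"][k]), 1e-9), 0.0),
                )
                c_k = CostInputs(
                    c_ed_visit=Moments(float(cost_draws["c_ed_visit"][k]), 0.0),
                    c_night=Moments(float(cost_draws["c_night"][k]), 0.0),
                    dev_total=cost_inputs.dev_total,
                    dev_per_patient=cost_inputs.dev_per_patient,
                    np_wage=cost_inputs.np_wage,
                    np_hours_dss=cost_inputs.np_hours_dss,
                    np_hours_nondss=cost_inputs.np_hours_nondss,
                    intervention_cost_per_patient=dict(
                        cost_inputs.intervention_cost_per_patient),
                )
                sim = run_cohort_simulation(
                    u_k, c_k, traj, config,
                    seed=inner_seeds[j * K + k],
                    n_patients=config.psa_inner,
                )
                costs[k, j] = sim.total_cost

    return PSAResult(
        arms=tuple(arms), costs=costs, effects=effects,
        seed=config.seed, config_hash=_config_hash(config),
    )


def nmb(cost, effect_score, wtp, anchor: float = EFFECT_ANCHOR):
    """Net monetary benefit: wtp * (anchor - burden) - cost.

    Burden reduction is measured against the fixed anchor (worst score 10);
    shifting the anchor moves every strategy's NMB equally, so pairwise
    comparisons — and hence acceptability — are anchor-invariant.
    """
    wtp = np.asarray(wtp, dtype=float)
    if np.any(wtp < 0):
        raise ValueError("willingness-to-pay must be >= 0")
    return wtp * (anchor - np.asarray(effect_score, dtype=float)) - np.asarray(
        cost, dtype=float)


@dataclass(frozen=True)
class CEACCurve:
    """Acceptability probabilities per arm over a willingness-to-pay grid."""

    wtp_grid: np.ndarray       # shape (W,)
    arms: tuple
    probabilities: np.ndarray  # shape (W, n_arms), rows sum to 1

    def to_frame(self) -> pd.DataFrame:
        """Plot-ready long format: (wtp, arm, probability)."""
        W, A = self.probabilities.shape
        return pd.DataFrame({
            "wtp": np.repeat(self.wtp_grid, A),
            "arm": [a.value for a in self.arms] * W,
            "probability": self.probabilities.ravel(),
        })


def ceac(psa_result: PSAResult, wtp_grid: Sequence[float]) -> CEACCurve:
    """Acceptability = share of draws with maximal NMB, ties split equally."""
    grid = np.asarray(list(wtp_grid), dtype=float)
    if grid.size == 0:
        raise ValueError("wtp_grid must be non-empty")
    if np.any(grid < 0):
        raise ValueError("willingness-to-pay must be >= 0")
    K, A = psa_result.costs.shape
    if K == 0:
        raise ValueError("PSA result has no draws")
    probs = np.empty((grid.size, A))
    reduction = EFFECT_ANCHOR - psa_result.effects  # (A,)
    for i, lam in enumerate(grid):
        m = lam * reduction[None, :] - psa_result.costs  # (K, A)
        best = m.max(axis=1, keepdims=True)
        tie = m == best
        probs[i] = (tie / tie.sum(axis=1, keepdims=True)).mean(axis=0)
    return CEACCurve(wtp_grid=grid, arms=psa_result.arms, probabilities=probs)
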