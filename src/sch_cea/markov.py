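"""Weekly-cycle Markov cohort engine.

Each arm's cohort starts Well; in every 1-week cycle a patient may have an
ED visit and/or an unplanned hospitalization (independent parallel events)
and returns to Well — no mortality state, no discounting over the 6-month
horizon.  Costs accrue as visit-count-scaled ED costs and LOS-scaled
per-night hospitalization costs; the intervention cost (with or without the
development share) is added once per patient.  Effectiveness is the
calibrated horizon-mean burden score and does not vary within the cohort.

Both a closed-form expectation and an individual-level microsimulation are
provided; the latter serves as a Monte Carlo check of the former.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .calibrate import intervention_cost
from .params import (
    Arm,
    CostInputs,
    ModelConfig,
    StrategyOutcome,
    SymptomTrajectory,
    UtilizationParams,
)

__all__ = [
    "expected_weekly_cost",
    "run_deterministic",
    "run_cohort_simulation",
    "base_case",
]


def expected_weekly_cost(
    u: UtilizationParams,
    c: CostInputs,
    include_visit_multiplier: bool = True,
) -> float:
    """Expected unplanned-utilization cost per patient-week.

    With the visit-count multipliers on (default), a week with any ED visit
    accrues the conditional visit count times the per-visit cost, and a week
    with any hospitalization accrues the conditional admission count times
    LOS nights times the per-night cost:

        p_ed * n_ed * c_ed  +  p_hosp * n_hosp * los * c_night

    With multipliers off the multiplicities are dropped (one event per
    event-week).  Missing conditional fields are treated as multiplicity 1;
    a missing LOS with nonzero hospitalization probability is an error.
    """
    n_ed = u.n_ed_given_any.mean if u.n_ed_given_any is not None else 1.0
    n_hosp = u.n_hosp_given_any.mean if u.n_hosp_given_any is not None else 1.0
    if u.los_days is None:
        if u.p_hosp_week.mean > 0:
            raise ValueError(
                f"los_days missing for arm {u.arm} with p_hosp_week > 0"
            )
        los = 0.0
    else:
        los = u.los_days.mean
    if not include_visit_multiplier:
        n_ed = n_hosp = 1.0
    return (
        u.p_ed_week.mean * n_ed * c.c_ed_visit.mean
        + u.p_hosp_week.mean * n_hosp * c.c_night.mean * los
    )


def run_deterministic(
    u: UtilizationParams,
    c: CostInputs,
    trajectory: SymptomTrajectory,
    config: ModelConfig,
) -> StrategyOutcome:
    """Closed-form 26-week per-patient expected cost and effectiveness."""
    if trajectory is None or trajectory.effect_score is None:
        raise ValueError(f"missing calibrated trajectory for arm {u.arm}")
    weekly = expected_weekly_cost(u, c, config.include_visit_multiplier)
    total = config.horizon_weeks * weekly + intervention_cost(
        u.arm, c, include_development=config.include_development
    )
    return StrategyOutcome(
        arm=u.arm,
        total_cost=float(total),
        effect_score=float(trajectory.effect_score),
        mc_se_cost=0.0,
    )


def run_cohort_simulation(
    u: UtilizationParams,
    c: CostInputs,
    trajectory: SymptomTrajectory,
    config: ModelConfig,
    seed: Optional[int] = None,
    n_patients: Optional[int] = None,
) -> StrategyOutcome:
    """Microsimulation of the cohort: mean per-patient cost with MC SE.

    Each of ``n_patients`` (default ``config.cohort_size``) hypothetical
    patients runs through ``horizon_weeks`` independent cycles.  Event
    multiplicities use 1 + Poisson(mean - 1) and LOS a continuous gamma with
    the calibrated mean/sd, so the simulation mean converges to the closed
    form.  ``seed`` is mandatory.
    """
    if seed is None:
        raise ValueError("seed is required (reproducibility contract)")
    if trajectory is None or trajectory.effect_score is None:
        raise ValueError(f"missing calibrated trajectory for arm {u.arm}")
    n = int(n_patients if n_patients is not None else config.cohort_size)
    T = config.horizon_weeks
    rng = np.random.default_rng(seed)

    ed_any = rng.random((n, T)) < u.p_ed_week.mean
    hosp_any = rng.random((n, T)) < u.p_hosp_week.mean
    cost = np.zeros(n)

    k = int(ed_any.sum())
    if k:
        mult = np.zeros((n, T))
        if config.include_visit_multiplier and u.n_ed_given_any is not None:
            mult[ed_any] = 1 + rng.poisson(
                max(u.n_ed_given_any.mean - 1.0, 0.0), size=k)
        else:
            mult[ed_any] = 1.0
        cost += mult.sum(axis=1) * c.c_ed_visit.mean

    k = int(hosp_any.sum())
    if k:
        if u.los_days is None:
            raise ValueError(f"los_days missing for arm {u.arm}")
        adm = np.zeros((n, T), dtype=int)
        if config.include_visit_multiplier and u.n_hosp_given_any is not None:
            adm[hosp_any] = 1 + rng.poisson(
                max(u.n_hosp_given_any.mean - 1.0, 0.0), size=k)
        else:
            adm[hosp_any] = 1
        total_adm = int(adm.sum())
        m, s = u.los_days.mean, u.los_days.sd
        if s > 0:
            los = rng.gamma((m / s) ** 2, s**2 / m, size=total_adm)
        else:
            los = np.full(total_adm, m)
        night_cost = np.zeros(n)
        pat_idx = np.broadcast_to(np.arange(n)[:, None], (n, T)).ravel()
        pat_of_adm = np.repeat(pat_idx, adm.ravel())
        np.add.at(night_cost, pat_of_adm, los)
        cost += night_cost * c.c_night.mean

    cost += intervention_cost(
        u.arm, c, include_development=config.include_development
    )
    se = float(np.std(cost, ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    return StrategyOutcome(
        arm=u.arm,
        total_cost=float(cost.mean()),
        effect_score=float(trajectory.effect_score),
        mc_se_cost=se,
    )


def base_case(
    calibration: dict,
    cost_inputs: CostInputs,
    config: ModelConfig,
) -> list:
    """Deterministic strategy outcomes for every calibrated arm.

    ``calibration`` maps arm -> (UtilizationParams, SymptomTrajectory);
    arms are evaluated in the canonical arm order.
    """
    out = []
    for arm in Arm:
        if arm not in calibration:
            continue
        u, traj = calibration[arm]
        out.append(run_deterministic(u, cost_inputs, traj, config))
    return out
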