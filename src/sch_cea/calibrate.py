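"""Calibration: patient-level records -> model input parameters.

Estimates, per arm, the weekly utilization inputs (event probabilities,
conditional visit multiplicities, length of stay), the weekly symptom-burden
trajectory with its quadratic fit and horizon-mean effectiveness score, and
converts (mean, sd) summaries into beta/gamma distributions for the
probabilistic sensitivity analysis.
"""

from __future__ import annotations

import logging
import math
from typing import Optional, Sequence, Tuple

import numpy as np

from .params import (
    Arm,
    CostInputs,
    DistParams,
    Moments,
    SymptomTrajectory,
    UtilizationParams,
)
from .synthcohort import SEVERITY_COLUMNS, TrialData, _weeks_on_study

__all__ = [
    "estimate_utilization",
    "weekly_burden",
    "interpolate_interior",
    "fit_quadratic_effect",
    "calibrate_trajectory",
    "trajectory_from_curve",
    "calibrate_all",
    "beta_from_moments",
    "gamma_from_moments",
    "intervention_cost",
]

logger = logging.getLogger(__name__)

HORIZON_WEEKS = 26


def _moments(x: np.ndarray) -> Moments:
    x = np.asarray(x, dtype=float)
    sd = float(np.std(x, ddof=1)) if x.size > 1 else 0.0
    return Moments(float(np.mean(x)), sd)


def _conditional_count(counts: np.ndarray) -> Optional[Moments]:
    """Mean multiplicity per event-week, pooled over event-weeks.

    ``counts`` are the per-week event counts restricted to weeks with >= 1
    event.  The pooled mean (total events / total event-weeks) is an
    unbiased estimator of the generating per-event-week multiplicity.
    Returns None (missing, not zero) when there are no event-weeks.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.size == 0:
        return None
    return _moments(counts)


def estimate_utilization(trial: TrialData, arm: Arm) -> UtilizationParams:
    """Estimate weekly utilization parameters for ``arm`` from trial records.

    The weekly event probability is the across-patient mean of each
    patient's proportion of on-study weeks with >= 1 event; its sd is the
    across-patient sd of those proportions (which is why the published sds
    exceed the binomial bound).  Conditional visit counts are pooled over
    event-weeks; LOS is pooled over hospitalizations.
    """
    arm = Arm(arm)
    pats = trial.patients[trial.patients["arm"] == arm.value]
    if pats.empty:
        raise ValueError(f"no records for arm {arm}")
    weeks_on = _weeks_on_study(pats["days_on_study"].to_numpy())
    weeks_on = np.minimum(weeks_on, HORIZON_WEEKS)

    ev = trial.events[trial.events["arm"] == arm.value]
    by_pat = ev.groupby("patient_id").agg(
        ed_weeks=("ed_visits", lambda c: int((c >= 1).sum())),
        hosp_weeks=("hosp_admissions", lambda c: int((c >= 1).sum())),
    )
    idx = pats["patient_id"].to_numpy()
    ed_weeks = by_pat["ed_weeks"].reindex(idx, fill_value=0).to_numpy()
    hosp_weeks = by_pat["hosp_weeks"].reindex(idx, fill_value=0).to_numpy()

    p_ed = _moments(ed_weeks / weeks_on)
    p_hosp = _moments(hosp_weeks / weeks_on)

    ed_counts = ev.loc[ev["ed_visits"] >= 1, "ed_visits"].to_numpy()
    hosp_counts = ev.loc[ev["hosp_admissions"] >= 1, "hosp_admissions"].to_numpy()
    st = trial.stays[trial.stays["arm"] == arm.value]
    los = st["los_days"].to_numpy()

    return UtilizationParams(
        arm=arm,
        p_ed_week=p_ed,
        n_ed_given_any=_conditional_count(ed_counts),
        p_hosp_week=p_hosp,
        n_hosp_given_any=_conditional_count(hosp_counts),
        los_days=_moments(los) if los.size else None,
    )


def weekly_burden(trial: TrialData, arm: Arm) -> SymptomTrajectory:
    """Weekly mean burden scores for ``arm`` (no fit yet).

    The daily burden is the mean severity across the 11 symptoms; each
    patient contributes the mean over their reported days in a week, and
    the weekly score averages those across patients on study that week.
    Weeks with no reported days are NaN (missing).
    """
    arm = Arm(arm)
    rep = trial.reports[(trial.reports["arm"] == arm.value)
                        & trial.reports["reported"]]
    if rep.empty:
        raise ValueError(f"no reported days for arm {arm}")
    daily = rep[SEVERITY_COLUMNS].mean(axis=1)
    per_patient_week = daily.groupby(
        [rep["patient_id"], rep["week"]]).mean()
    by_week = per_patient_week.groupby(level="week").mean()

    scores = np.full(HORIZON_WEEKS, np.nan)
    weeks = by_week.index.to_numpy(dtype=int)
    scores[weeks - 1] = by_week.to_numpy()
    return SymptomTrajectory(arm=arm, weekly_scores=tuple(scores))


def interpolate_interior(weekly_scores: Sequence[float]) -> np.ndarray:
    """Linearly interpolate interior missing weeks; leading/trailing stay NaN."""
    s = np.asarray(weekly_scores, dtype=float).copy()
    ok = np.flatnonzero(~np.isnan(s))
    if ok.size >= 2:
        inner = np.arange(ok[0], ok[-1] + 1)
        s[inner] = np.interp(inner, ok, s[ok])
    return s


def fit_quadratic_effect(
    weekly_scores: Sequence[float],
    horizon: int = HORIZON_WEEKS,
) -> Tuple[tuple, float]:
    """Fit S(t) = a + b t + c t^2 to weekly scores and integrate.

    Weeks are indexed t = 1..26; interior missing weeks are linearly
    interpolated first, trailing/leading missing weeks are left out of the
    fit (the quadratic extrapolates over them).  The effectiveness score is
    the horizon mean (1/T) * int_0^T S(t) dt = a + b T/2 + c T^2/3, clipped
    to the 0-10 burden scale.

    Returns ``((a, b, c), effect_score)``.
    """
    s = interpolate_interior(weekly_scores)
    t = np.arange(1, len(s) + 1, dtype=float)
    ok = ~np.isnan(s)
    if ok.sum() < 3:
        raise ValueError(
            f"need >= 3 non-missing weekly scores, got {int(ok.sum())}"
        )
    c, b, a = np.polyfit(t[ok], s[ok], 2)
    T = float(horizon)
    effect = a + b * T / 2.0 + c * T**2 / 3.0
    return (float(a), float(b), float(c)), float(np.clip(effect, 0.0, 10.0))


def calibrate_trajectory(
    trial: TrialData, arm: Arm, horizon: int = HORIZON_WEEKS
) -> SymptomTrajectory:
    """Weekly burden scores plus quadratic fit and effectiveness score."""
    traj = weekly_burden(trial, arm)
    coeffs, effect = fit_quadratic_effect(traj.weekly_scores, horizon)
    return SymptomTrajectory(
        arm=traj.arm,
        weekly_scores=traj.weekly_scores,
        quad_coeffs=coeffs,
        effect_score=effect,
    )


def trajectory_from_curve(
    arm: Arm, curve: Sequence[float], horizon: int = HORIZON_WEEKS
) -> SymptomTrajectory:
    """Trajectory calibrated from a configured weekly burden curve.

    Evaluates the curve at weeks 1..26 and fits/integrates exactly as for
    trial-derived weekly scores; used when the weekly series is supplied as
    a published input rather than estimated from patient records.
    """
    from .synthcohort import evaluate_burden_curve

    weeks = np.arange(1, HORIZON_WEEKS + 1)
    scores = np.clip(evaluate_burden_curve(curve, weeks), 0.0, 10.0)
    coeffs, effect = fit_quadratic_effect(scores, horizon)
    return SymptomTrajectory(
        arm=Arm(arm), weekly_scores=tuple(scores),
        quad_coeffs=coeffs, effect_score=effect,
    )


def calibrate_all(trial: TrialData, horizon: int = HORIZON_WEEKS) -> dict:
    """Per-arm (UtilizationParams, SymptomTrajectory) from trial records."""
    out = {}
    for arm in trial.arms():
        out[arm] = (
            estimate_utilization(trial, arm),
            calibrate_trajectory(trial, arm, horizon),
        )
    return out


# --- PSA distribution parameterization ------------------------------------

def beta_from_moments(mean: float, sd: float) -> DistParams:
    """Method-of-moments beta for a probability with the given mean/sd.

    alpha = mean * nu, beta = (1 - mean) * nu with
    nu = mean (1 - mean) / sd^2 - 1.  When the sd is infeasibly large
    (sd^2 >= mean (1 - mean)), it is shrunk to 0.95 * sqrt(mean (1 - mean))
    with a warning so the PSA stays runnable.  sd = 0 yields a point mass.
    """
    if not 0.0 < mean < 1.0:
        raise ValueError(f"mean must lie in (0, 1), got {mean}")
    if sd < 0:
        raise ValueError(f"sd must be >= 0, got {sd}")
    if sd == 0.0:
        return DistParams("beta", (), mean, 0.0)
    bound = mean * (1.0 - mean)
    if sd**2 >= bound:
        shrunk = 0.95 * math.sqrt(bound)
        logger.warning(
            "beta_from_moments: sd %.4g infeasible for mean %.4g; shrunk to %.4g",
            sd, mean, shrunk,
        )
        sd = shrunk
    nu = bound / sd**2 - 1.0
    return DistParams("beta", (mean * nu, (1.0 - mean) * nu), mean, sd)


def gamma_from_moments(mean: float, sd: float) -> DistParams:
    """Method-of-moments gamma: shape = (mean/sd)^2, scale = sd^2/mean."""
    if mean <= 0:
        raise ValueError(f"mean must be > 0, got {mean}")
    if sd < 0:
        raise ValueError(f"sd must be >= 0, got {sd}")
    if sd == 0.0:
        return DistParams("gamma", (), mean, 0.0)
    return DistParams("gamma", ((mean / sd) ** 2, sd**2 / mean), mean, sd)


def intervention_cost(
    arm: Arm,
    cost_inputs: CostInputs,
    include_development: bool = True,
    dev_per_patient: Optional[float] = None,
) -> float:
    """Per-patient intervention cost for ``arm``, 2023 USD.

    The published per-patient totals embed a uniform development share
    (``cost_inputs.dev_per_patient``); ``include_development=False`` (or an
    explicit ``dev_per_patient`` override) strips or rescales that share,
    leaving the arm's labor component.
    """
    arm = Arm(arm)
    share = cost_inputs.dev_per_patient if dev_per_patient is None else dev_per_patient
    if not include_development:
        share = 0.0
    return cost_inputs.labor_component(arm) + share
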