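"""Incremental cost-effectiveness analysis over the five strategies.

Effectiveness is a burden score (lower better); internally every strategy
is scored as burden *reduction* relative to a fixed anchor of 10 (the worst
possible score), so "more effective" means a larger reduction and ICERs —
dollars per 1-point burden reduction — are anchor-invariant.

Classification follows the standard frontier construction: strategies that
are absolutely dominated (at least as costly and at least as ineffective as
another, strictly so in one dimension) are removed; then extended dominance
iteratively removes any strategy whose incremental ICER exceeds that of the
next more effective frontier strategy, until frontier ICERs increase
strictly with cost.  The least costly survivor is the reference.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence

import pandas as pd

from .params import Arm, StrategyOutcome

__all__ = ["STATUS_VALUES", "FrontierResult", "icer", "find_frontier", "frontier_table"]

EFFECT_ANCHOR = 10.0  # worst possible burden score

STATUS_VALUES = (
    "reference",
    "on_frontier",
    "absolutely_dominated",
    "extendedly_dominated",
)


def icer(a: StrategyOutcome, b: StrategyOutcome) -> float:
    """Incremental cost per 1-point burden reduction of ``b`` over ``a``.

    ``b`` must be strictly more effective (lower burden score) than ``a``;
    the denominator is the score decrease, so the ICER is
    (cost_b - cost_a) / (effect_a - effect_b).
    """
    de = a.effect_score - b.effect_score
    if de <= 0:
        raise ValueError(
            "icer undefined: second strategy must have strictly lower "
            f"burden score ({b.effect_score} vs {a.effect_score}); "
            "compare by dominance instead"
        )
    return (b.total_cost - a.total_cost) / de


@dataclass(frozen=True)
class FrontierResult:
    """Dominance classification and frontier ICERs.

    ``status`` maps every arm to one of :data:`STATUS_VALUES`;
    ``ordering`` lists frontier arms by increasing cost (reference first);
    ``icers`` maps each non-reference frontier arm to its ICER versus the
    previous frontier arm.
    """

    status: Dict[Arm, str]
    ordering: List[Arm]
    icers: Dict[Arm, float]

    @property
    def reference(self) -> Arm:
        return self.ordering[0]

    @property
    def dominated(self) -> List[Arm]:
        return [a for a, s in self.status.items() if s.endswith("dominated")]


def find_frontier(outcomes: Sequence[StrategyOutcome]) -> FrontierResult:
    """Classify strategies and build the efficiency frontier."""
    outcomes = list(outcomes)
    if not outcomes:
        raise ValueError("need at least one strategy outcome")
    arms = [o.arm for o in outcomes]
    if len(set(arms)) != len(arms):
        raise ValueError("duplicate arms in outcomes")

    # Sort by cost; ties broken by better effect (lower burden), then by
    # canonical arm order so classification is deterministic.
    order = sorted(
        outcomes,
        key=lambda o: (o.total_cost, o.effect_score, list(Arm).index(o.arm)),
    )

    status: Dict[Arm, str] = {}
    for i, o in enumerate(order):
        dominated = False
        for j, other in enumerate(order):
            if i == j:
                continue
            le_cost = other.total_cost <= o.total_cost
            le_burden = other.effect_score <= o.effect_score
            strict = (other.total_cost < o.total_cost
                      or other.effect_score < o.effect_score)
            if le_cost and le_burden and strict:
                dominated = True
                break
            # exact tie in both: the earlier strategy in the sort wins
            if (j < i and other.total_cost == o.total_cost
                    and other.effect_score == o.effect_score):
                dominated = True
                break
        if dominated:
            status[o.arm] = "absolutely_dominated"

    chain = [o for o in order if o.arm not in status]
    # after absolute dominance, chain has strictly increasing cost and
    # strictly decreasing burden; enforce strictly increasing ICERs
    while len(chain) > 2:
        icers_seq = [icer(chain[k - 1], chain[k]) for k in range(1, len(chain))]
        removed = False
        for k in range(1, len(chain) - 1):
            if icers_seq[k - 1] >= icers_seq[k]:
                status[chain[k].arm] = "extendedly_dominated"
                del chain[k]
                removed = True
                break
        if not removed:
            break

    icers: Dict[Arm, float] = {}
    for k, o in enumerate(chain):
        if k == 0:
            status[o.arm] = "reference"
        else:
            status[o.arm] = "on_frontier"
            icers[o.arm] = icer(chain[k - 1], o)
    return FrontierResult(
        status=status,
        ordering=[o.arm for o in chain],
        icers=icers,
    )


def frontier_table(
    outcomes: Sequence[StrategyOutcome], result: FrontierResult
) -> pd.DataFrame:
    """Report-shaped table: arm, cost, effectiveness, status, ICER.

    Rows are ordered frontier first (by cost), then dominated strategies by
    cost; the ICER column is empty for the reference and dominated rows.
    """
    by_arm = {o.arm: o for o in outcomes}
    ordered = list(result.ordering) + sorted(
        (a for a in by_arm if a not in result.ordering),
        key=lambda a: by_arm[a].total_cost,
    )
    rows = []
    for arm in ordered:
        o = by_arm[arm]
        rows.append({
            "arm": arm.value,
            "cost": o.total_cost,
            "effectiveness": o.effect_score,
            "status": result.status[arm],
            "icer": result.icers.get(arm, float("nan")),
        })
    return pd.DataFrame(rows)
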