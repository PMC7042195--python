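"""Cost-effectiveness assembly: strategy summaries, ICERs, dominance frontier.

Expected lifetime cost of a strategy is its undiscounted upfront
(screening + early-intervention) outlay plus the mixture-weighted
discounted Markov cost streams; expected QALYs are the mixture-weighted
discounted Markov QALY streams.  Strategies are ordered least to most
effective, strongly and extendedly dominated entries are flagged, and
incremental ICERs along the surviving frontier are strictly increasing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .decision_tree import (
    Strategy,
    default_strategies,
    expected_upfront_cost,
    outcome_mixture,
    relative_risk_id,
)
from .markov import LifeTable, MODEL_START_AGE, markov_payoff
from .parameters import OUTCOME_CLASSES, ParameterSet, Perspective, ValidationError

__all__ = [
    "UndefinedICERError",
    "DominantComparatorError",
    "StrategySummary",
    "CEAEntry",
    "CEAResult",
    "summarize_strategy",
    "summarize_all",
    "icer",
    "frontier",
    "common_baseline_icers",
    "optimal_strategy",
    "net_monetary_benefit",
    "results_table",
]


class UndefinedICERError(ValueError):
    """Incremental QALYs are zero; the ratio is undefined."""


class DominantComparatorError(ValueError):
    """The comparator gains QALYs at lower cost; no ratio is reported."""


@dataclass(frozen=True)
class StrategySummary:
    """Expected discounted lifetime cost/QALYs of one strategy under one perspective."""

    strategy: Strategy
    perspective: Perspective
    expected_cost: float
    expected_qalys: float
    id_prevalence: float
    rr_vs_baseline: float | None = None

    @property
    def label(self) -> str:
        return self.strategy.label


def summarize_strategy(
    strategy: Strategy,
    params: ParameterSet,
    lt: LifeTable,
    perspective: Perspective,
    baseline: Strategy | None = None,
    start_age: int = MODEL_START_AGE,
) -> StrategySummary:
    """Fold the decision tree into the Markov payoffs for one strategy."""
    mixture = outcome_mixture(strategy, params)
    payoffs = {
        cls: markov_payoff(cls, params, lt, perspective, start_age)
        for cls in OUTCOME_CLASSES
    }
    cost = expected_upfront_cost(strategy, params, perspective) + sum(
        mixture.fraction(cls) * payoffs[cls].discounted_cost for cls in OUTCOME_CLASSES
    )
    qalys = sum(
        mixture.fraction(cls) * payoffs[cls].discounted_qalys for cls in OUTCOME_CLASSES
    )
    rr = None
    if baseline is not None and outcome_mixture(baseline, params).f_asd_id > 0.0:
        rr = relative_risk_id(strategy, params, baseline)
    return StrategySummary(
        strategy=strategy,
        perspective=perspective,
        expected_cost=cost,
        expected_qalys=qalys,
        id_prevalence=mixture.f_asd_id,
        rr_vs_baseline=rr,
    )


def summarize_all(
    params: ParameterSet,
    lt: LifeTable,
    perspective: Perspective,
    strategies: Sequence[Strategy] | None = None,
    baseline_label: str = "status_quo",
    start_age: int = MODEL_START_AGE,
) -> list[StrategySummary]:
    """Summaries for all strategies, with ID relative risks vs the baseline."""
    if strategies is None:
        strategies = default_strategies(params)
    baseline = next((s for s in strategies if s.label == baseline_label), None)
    return [
        summarize_strategy(s, params, lt, perspective, baseline, start_age)
        for s in strategies
    ]


def icer(higher: StrategySummary, lower: StrategySummary) -> float:
    """Incremental cost-effectiveness ratio of ``higher`` over ``lower``."""
    if higher.perspective.label != lower.perspective.label:
        raise ValidationError("ICER comparators must share a perspective")
    d_cost = higher.expected_cost - lower.expected_cost
    d_qalys = higher.expected_qalys - lower.expected_qalys
    if d_qalys == 0.0:
        raise UndefinedICERError(
            f"{higher.label} vs {lower.label}: zero incremental QALYs, ICER undefined"
        )
    if d_qalys > 0.0 and d_cost < 0.0:
        raise DominantComparatorError(
            f"{higher.label} dominates {lower.label} (more QALYs at lower cost)"
        )
    return d_cost / d_qalys


def _ratio(d_cost: float, d_qalys: float) -> float:
    """Signed cost-per-QALY ratio with infinities at zero incremental effect."""
    if d_qalys == 0.0:
        return math.copysign(math.inf, d_cost) if d_cost != 0.0 else 0.0
    return d_cost / d_qalys


@dataclass(frozen=True)
class CEAEntry:
    summary: StrategySummary
    dominance: str = "none"  # none | strong | extended
    icer: float | None = None  # vs previous non-dominated entry
    common_baseline_icer: float | None = None

    @property
    def label(self) -> str:
        return self.summary.label


@dataclass(frozen=True)
class CEAResult:
    """Frontier analysis: entries ordered least to most effective."""

    entries: tuple[CEAEntry, ...]

    @property
    def nondominated(self) -> tuple[CEAEntry, ...]:
        return tuple(e for e in self.entries if e.dominance == "none")

    def entry(self, label: str) -> CEAEntry:
        for e in self.entries:
            if e.label == label:
                return e
        raise ValidationError(f"no strategy {label!r} in this analysis")


def frontier(
    summaries: Sequence[StrategySummary], baseline_label: str = "status_quo"
) -> CEAResult:
    """Dominance analysis over a strategy set.

    Strongly dominated entries (another strategy is no less effective at
    no more cost, strictly better in one) are removed first; extendedly
    dominated entries (incremental ICER at or above a more effective
    successor's) are removed iteratively.  Surviving ICERs are strictly
    increasing.  Equal-effect ties break toward lower cost, equal-cost
    ties toward higher effect.
    """
    if len(summaries) < 2:
        raise ValidationError("frontier needs at least two strategy summaries")
    if len({s.perspective.label for s in summaries}) != 1:
        raise ValidationError("frontier summaries must share a perspective")

    order = sorted(summaries, key=lambda s: (s.expected_qalys, s.expected_cost))
    dominance = ["none"] * len(order)
    for i, s in enumerate(order):
        for j, other in enumerate(order):
            if i == j:
                continue
            if (
                other.expected_cost <= s.expected_cost
                and other.expected_qalys >= s.expected_qalys
                and (
                    other.expected_cost < s.expected_cost
                    or other.expected_qalys > s.expected_qalys
                )
            ):
                dominance[i] = "strong"
                break
            # exact duplicate: keep the first occurrence only
            if (
                j < i
                and other.expected_cost == s.expected_cost
                and other.expected_qalys == s.expected_qalys
            ):
                dominance[i] = "strong"
                break

    surviving = [i for i, d in enumerate(dominance) if d == "none"]
    while True:
        icers = [
            _ratio(
                order[b].expected_cost - order[a].expected_cost,
                order[b].expected_qalys - order[a].expected_qalys,
            )
            for a, b in zip(surviving, surviving[1:])
        ]
        removed = False
        for k in range(len(icers) - 1):
            if icers[k] >= icers[k + 1]:
                dominance[surviving[k + 1]] = "extended"
                surviving.pop(k + 1)
                removed = True
                break
        if not removed:
            break

    frontier_icers: dict[int, float] = {}
    for a, b in zip(surviving, surviving[1:]):
        frontier_icers[b] = _ratio(
            order[b].expected_cost - order[a].expected_cost,
            order[b].expected_qalys - order[a].expected_qalys,
        )

    baseline = next((s for s in order if s.label == baseline_label), None)
    entries = []
    for i, s in enumerate(order):
        common = None
        if baseline is not None and s.label != baseline.label:
            common = _ratio(
                s.expected_cost - baseline.expected_cost,
                s.expected_qalys - baseline.expected_qalys,
            )
        entries.append(
            CEAEntry(
                summary=s,
                dominance=dominance[i],
                icer=frontier_icers.get(i),
                common_baseline_icer=common,
            )
        )
    return CEAResult(entries=tuple(entries))


def common_baseline_icers(
    summaries: Sequence[StrategySummary], baseline: StrategySummary
) -> dict[str, float]:
    """Each strategy's ICER against a fixed common baseline (baseline skipped)."""
    out = {}
    for s in summaries:
        if s.label == baseline.label:
            continue
        out[s.label] = icer(s, baseline)
    return out


def optimal_strategy(cea: CEAResult, wtp: float) -> Strategy:
    """Most effective non-dominated strategy whose incremental ICER is within WTP.

    Falls back to the least costly (least effective frontier) strategy when
    no incremental ICER clears the threshold.
    """
    best = cea.nondominated[0].summary.strategy
    for e in cea.nondominated[1:]:
        if e.icer is not None and e.icer <= wtp:
            best = e.summary.strategy
    return best


def net_monetary_benefit(summary: StrategySummary, wtp: float) -> float:
    return summary.expected_qalys * wtp - summary.expected_cost


def results_table(cea: CEAResult) -> pd.DataFrame:
    """Reported-style table: costs to whole dollars, QALYs/prevalences to 4 d.p."""
    rows = []
    for e in cea.entries:
        s = e.summary
        rows.append(
            {
                "strategy": s.label,
                "lifetime_cost": round(s.expected_cost),
                "qalys": round(s.expected_qalys, 4),
                "icer": None if e.icer is None else round(e.icer),
                "icer_vs_baseline": None
                if e.common_baseline_icer is None
                else round(e.common_baseline_icer),
                "id_prevalence": round(s.id_prevalence, 4),
                "id_relative_risk": None
                if s.rr_vs_baseline is None
                else round(s.rr_vs_baseline, 4),
                "dominance": e.dominance,
            }
        )
    return pd.DataFrame(rows)
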