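"""One-way (tornado) and probabilistic (Monte Carlo) sensitivity analyses.

The default target quantity is the societal ICER of Test & Treat at
6 months versus the Status Quo.  One-way analysis re-runs the full
pipeline twice per parameter (low and high end of its tested range, all
else at base case); the probabilistic analysis propagates seeded draws of
the distribution-specified parameters through the full pipeline and
summarises the incremental cost/effect cloud on the CE plane.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cea import StrategySummary, summarize_strategy
from .decision_tree import Strategy
from .markov import LifeTable, MODEL_START_AGE
from .parameters import (
    DistributionSpec,
    ParameterSet,
    Perspective,
    ValidationError,
    apply_override,
    sample_parameter_draws,
)

__all__ = [
    "ModelContext",
    "TornadoEntry",
    "PSAResult",
    "CEPlaneSummary",
    "incremental_pair",
    "one_way",
    "tornado",
    "run_psa",
    "ce_plane_summary",
    "tornado_table",
    "psa_scatter_table",
]


@dataclass(frozen=True)
class ModelContext:
    """Everything needed to evaluate one incremental comparison."""

    params: ParameterSet
    life_table: LifeTable
    perspective: Perspective
    baseline_label: str = "status_quo"
    comparator_label: str = "test_treat_6"
    start_age: int = MODEL_START_AGE

    def summaries(self, params: ParameterSet | None = None) -> tuple[StrategySummary, StrategySummary]:
        p = self.params if params is None else params
        baseline = Strategy.from_label(self.baseline_label, p)
        comparator = Strategy.from_label(self.comparator_label, p)
        return (
            summarize_strategy(baseline, p, self.life_table, self.perspective, start_age=self.start_age),
            summarize_strategy(comparator, p, self.life_table, self.perspective, start_age=self.start_age),
        )


def incremental_pair(ctx: ModelContext, params: ParameterSet | None = None) -> tuple[float, float]:
    """(incremental cost, incremental QALYs) of the comparator vs the baseline."""
    base, comp = ctx.summaries(params)
    return (
        comp.expected_cost - base.expected_cost,
        comp.expected_qalys - base.expected_qalys,
    )


def _signed_icer(d_cost: float, d_qalys: float) -> float:
    if d_qalys == 0.0:
        return math.copysign(math.inf, d_cost) if d_cost != 0.0 else 0.0
    return d_cost / d_qalys


@dataclass(frozen=True)
class TornadoEntry:
    parameter: str
    low_input: float
    high_input: float
    icer_at_low: float
    icer_at_high: float

    @property
    def bar_width(self) -> float:
        return abs(self.icer_at_high - self.icer_at_low)


def one_way(ctx: ModelContext, parameter: str, low: float, high: float) -> TornadoEntry:
    """Re-run the pipeline with one parameter at each end of its range."""
    if low > high:
        raise ValidationError(f"one-way range for {parameter!r} has low > high")
    icers = []
    for value in (low, high):
        p = apply_override(ctx.params, parameter, value)
        icers.append(_signed_icer(*incremental_pair(ctx, p)))
    return TornadoEntry(
        parameter=parameter,
        low_input=low,
        high_input=high,
        icer_at_low=icers[0],
        icer_at_high=icers[1],
    )


def _relevant(parameter: str, ctx: ModelContext) -> bool:
    """Drop test characteristics of strategies outside the target comparison."""
    active = {ctx.baseline_label, ctx.comparator_label}
    if parameter in ("sens_mri_6", "spec_mri_6"):
        return "test_treat_6" in active
    if parameter in ("sens_mri_12", "spec_mri_12"):
        return "test_treat_12" in active
    return True


def tornado(
    ctx: ModelContext, ranges: Mapping[str, tuple[float, float]]
) -> list[TornadoEntry]:
    """One-way entries for every ranged parameter, widest bar first.

    Parameters that cannot affect the target comparison (the test
    characteristics of an uninvolved strategy) are skipped.
    """
    entries = [
        one_way(ctx, name, lo, hi)
        for name, (lo, hi) in ranges.items()
        if _relevant(name, ctx)
    ]
    return sorted(entries, key=lambda e: e.bar_width, reverse=True)


def tornado_table(entries: Sequence[TornadoEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "parameter": e.parameter,
                "low": e.low_input,
                "high": e.high_input,
                "icer_low": e.icer_at_low,
                "icer_high": e.icer_at_high,
                "width": e.bar_width,
            }
            for e in entries
        ],
        columns=["parameter", "low", "high", "icer_low", "icer_high", "width"],
    )


@dataclass(frozen=True)
class PSAResult:
    """Seeded Monte Carlo incremental cost/effect draws for one comparison."""

    n: int
    seed: int
    baseline_label: str
    comparator_label: str
    delta_cost: np.ndarray
    delta_qalys: np.ndarray
    draws: dict[str, np.ndarray] = field(default_factory=dict)


def run_psa(
    ctx: ModelContext,
    specs: Mapping[str, DistributionSpec],
    n: int,
    seed: int,
) -> PSAResult:
    """Propagate ``n`` seeded parameter draws through the full pipeline.

    Each draw builds a complete sampled parameter set (unsampled
    parameters stay at base), re-runs decision tree + Markov for baseline
    and comparator, and records the incremental pair.  Identical seeds
    yield bitwise-identical results.
    """
    if n < 1:
        raise ValidationError(f"PSA needs n >= 1 draws, got {n}")
    draws = sample_parameter_draws(specs, n, seed)  # validates specs up front
    d_cost = np.empty(n)
    d_qalys = np.empty(n)
    for i in range(n):
        sampled = ctx.params.replace(
            allow_qol_overlap=True, **{name: float(arr[i]) for name, arr in draws.items()}
        )
        d_cost[i], d_qalys[i] = incremental_pair(ctx, sampled)
    return PSAResult(
        n=n,
        seed=seed,
        baseline_label=ctx.baseline_label,
        comparator_label=ctx.comparator_label,
        delta_cost=d_cost,
        delta_qalys=d_qalys,
        draws=draws,
    )


@dataclass(frozen=True)
class CEPlaneSummary:
    """Quadrant shares of the CE plane and WTP-threshold acceptance shares.

    ``icer_below[wtp]`` is the share of draws with a QALY gain whose ICER
    falls below ``wtp`` (cost-saving draws included); draws losing QALYs
    are reported in their quadrants and excluded from the threshold shares.
    """

    quadrants: dict[str, float]
    icer_below: dict[float, float]


def ce_plane_summary(psa: PSAResult, wtp_list: Sequence[float] = (50000.0, 100000.0)) -> CEPlaneSummary:
    de, dc = psa.delta_qalys, psa.delta_cost
    n = psa.n
    quadrants = {
        "superior": float(np.mean((de > 0) & (dc < 0))),
        "more_effective_more_costly": float(np.mean((de > 0) & (dc >= 0))),
        "inferior": float(np.mean((de <= 0) & (dc >= 0))),
        "less_effective_less_costly": float(np.mean((de <= 0) & (dc < 0))),
    }
    gain = de > 0
    icer_below = {}
    for wtp in wtp_list:
        ok = gain & (dc < wtp * de)
        icer_below[float(wtp)] = float(np.mean(ok))
    return CEPlaneSummary(quadrants=quadrants, icer_below=icer_below)


def psa_scatter_table(psa: PSAResult) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "draw": np.arange(psa.n),
            "d_cost": psa.delta_cost,
            "d_qaly": psa.delta_qalys,
        }
    )
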