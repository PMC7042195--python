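"""Two-state (alive/dead) Markov cohort engine.

A cohort enters at age 6 and moves through annual cycles until the life
table's terminal age.  Mortality in each cycle is the life-table annual
death probability scaled on the cumulative-hazard scale by the outcome
class's hazard ratio, ``q' = 1 - (1 - q)**hr`` — naive multiplication
would exceed 1 at the with-ID hazard ratio.  Rewards (utility weights and
age-banded annual costs) accrue at cycle start with no half-cycle
correction, and both streams are discounted at the configured annual rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .parameters import (
    CostSchedule,
    OUTCOME_CLASSES,
    ParameterSet,
    Perspective,
    ValidationError,
)

__all__ = [
    "MODEL_START_AGE",
    "LifeTable",
    "read_life_table",
    "write_life_table",
    "CohortTrace",
    "QolSchedule",
    "MarkovPayoff",
    "adjust_mortality",
    "cohort_trace",
    "discounted_qalys",
    "discounted_costs",
    "life_expectancy",
    "markov_payoff",
]

#: age at which the cohort enters the Markov model
MODEL_START_AGE = 6


@dataclass(frozen=True)
class LifeTable:
    """Annual death probabilities q(x) on a gap-free age grid.

    ``q[i]`` is the probability of dying between ages ``start_age + i`` and
    ``start_age + i + 1``; the terminal entry must be 1 so every cohort is
    extinguished by the terminal age.
    """

    start_age: int
    q: np.ndarray

    def __post_init__(self) -> None:
        q = np.asarray(self.q, dtype=float)
        object.__setattr__(self, "q", q)
        if q.ndim != 1 or len(q) == 0:
            raise ValidationError("life table needs a one-dimensional, non-empty q sequence")
        if np.any((q < 0) | (q > 1)):
            raise ValidationError("life-table death probabilities must lie in [0, 1]")
        if q[-1] != 1.0:
            raise ValidationError(
                f"life table must end with q = 1 at the terminal age, got {q[-1]}"
            )

    @property
    def terminal_age(self) -> int:
        return self.start_age + len(self.q) - 1

    def q_from(self, age: int) -> np.ndarray:
        """Death probabilities from ``age`` through the terminal age."""
        if age < self.start_age or age > self.terminal_age:
            raise ValidationError(
                f"life table covers ages {self.start_age}-{self.terminal_age}; age {age} missing"
            )
        return self.q[age - self.start_age :]

    def to_frame(self) -> pd.DataFrame:
        ages = self.start_age + np.arange(len(self.q))
        return pd.DataFrame({"age": ages, "qx": self.q})


def read_life_table(path) -> LifeTable:
    """Read a life table from two-column delimited text (header ``age,qx``)."""
    df = pd.read_csv(path)
    missing = {"age", "qx"} - set(df.columns)
    if missing:
        raise ValidationError(f"life-table file {path} lacks column(s) {sorted(missing)}")
    df = df.sort_values("age")
    ages = df["age"].to_numpy(dtype=int)
    if np.any(np.diff(ages) != 1):
        gap = int(ages[np.flatnonzero(np.diff(ages) != 1)[0]] + 1)
        raise ValidationError(f"life-table file {path} has a gap at age {gap}")
    return LifeTable(start_age=int(ages[0]), q=df["qx"].to_numpy(dtype=float))


def write_life_table(lt: LifeTable, path) -> None:
    lt.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class CohortTrace:
    """Surviving cohort fraction S(t) per annual cycle, S(0) = 1.

    Cycle ``t`` occupies attained age ``start_age + t``; the final entry is
    the (zero) fraction alive after the terminal age's cycle.
    """

    start_age: int
    survival: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.survival, dtype=float)
        object.__setattr__(self, "survival", s)
        if s[0] != 1.0:
            raise ValidationError("cohort trace must start at S(0) = 1")
        if np.any(np.diff(s) > 1e-15) or np.any((s < 0) | (s > 1)):
            raise ValidationError("cohort survival must be non-increasing within [0, 1]")

    @property
    def n_cycles(self) -> int:
        """Number of reward-accruing cycles (the final zero entry accrues none)."""
        return len(self.survival) - 1

    @property
    def cycle_ages(self) -> np.ndarray:
        return self.start_age + np.arange(self.n_cycles)


def adjust_mortality(q, hr: float):
    """Hazard-scale mortality adjustment ``1 - (1 - q)**hr``, capped at 1."""
    q = np.asarray(q, dtype=float)
    if np.any((q < 0) | (q > 1)):
        raise ValidationError("annual death probability must lie in [0, 1]")
    if hr <= 0:
        raise ValidationError(f"hazard ratio must be positive, got {hr}")
    out = np.minimum(1.0 - (1.0 - q) ** hr, 1.0)
    return float(out) if out.ndim == 0 else out


def cohort_trace(lt: LifeTable, hr: float, start_age: int = MODEL_START_AGE) -> CohortTrace:
    """Survival trace of a cohort entering at ``start_age`` under hazard ratio ``hr``."""
    q = adjust_mortality(lt.q_from(start_age), hr)
    survival = np.concatenate([[1.0], np.cumprod(1.0 - q)])
    return CohortTrace(start_age=start_age, survival=survival)


@dataclass(frozen=True)
class QolSchedule:
    """Utility weight by age: constant in childhood, optionally declining in adulthood."""

    base_weight: float
    decline_per_year: float = 0.0
    decline_start_age: int = 18
    floor: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.base_weight <= 1.0:
            raise ValidationError("base_weight must lie in [0, 1]")
        if self.decline_per_year < 0:
            raise ValidationError("decline_per_year must be non-negative")
        if not 0.0 <= self.floor <= self.base_weight:
            raise ValidationError("floor must lie in [0, base_weight]")

    def weights(self, ages: np.ndarray) -> np.ndarray:
        years_declining = np.maximum(0, np.asarray(ages) - self.decline_start_age)
        w = self.base_weight - self.decline_per_year * years_declining
        return np.clip(w, self.floor, self.base_weight)


@dataclass(frozen=True)
class MarkovPayoff:
    discounted_qalys: float
    discounted_cost: float
    life_expectancy: float


def _discount_factors(n: int, r: float) -> np.ndarray:
    if r < 0:
        raise ValidationError(f"discount rate must be non-negative, got {r}")
    return (1.0 + r) ** -np.arange(n, dtype=float)


def discounted_qalys(trace: CohortTrace, qol: QolSchedule, r: float) -> float:
    """Sum of S(t) * w(age) / (1+r)^t over cycles, rewards at cycle start."""
    s = trace.survival[: trace.n_cycles]
    w = qol.weights(trace.cycle_ages)
    return float(np.sum(s * w * _discount_factors(trace.n_cycles, r)))


def discounted_costs(
    trace: CohortTrace,
    schedule: CostSchedule,
    outcome_class: str,
    perspective: Perspective,
    r: float,
) -> float:
    """Discounted lifetime annual-cost stream; band lookup by age at cycle start."""
    s = trace.survival[: trace.n_cycles]
    c = schedule.costs_for_ages(trace.cycle_ages, outcome_class)
    c = c * perspective.annual_cost_fraction
    return float(np.sum(s * c * _discount_factors(trace.n_cycles, r)))


def life_expectancy(trace: CohortTrace) -> float:
    """Expected whole remaining years, sum of S(t) for t >= 1."""
    return float(trace.survival[1:].sum())


_CLASS_HR = {"non_asd": None, "asd_only": "hr_asd", "asd_id": "hr_asd_id"}
_CLASS_QOL = {"non_asd": None, "asd_only": "qol_asd", "asd_id": "qol_asd_id"}


def markov_payoff(
    outcome_class: str,
    params: ParameterSet,
    lt: LifeTable,
    perspective: Perspective,
    start_age: int = MODEL_START_AGE,
) -> MarkovPayoff:
    """Lifetime discounted QALYs, costs and life expectancy for one outcome class.

    The class selects the mortality hazard ratio, the utility weight and
    the annual cost row: general-population mortality, weight 1 and zero
    ASD-related cost for the non-ASD class; the configured ASD or ASD+ID
    values otherwise.  The adult utility decline (when enabled) applies to
    the ASD classes only.
    """
    if outcome_class not in OUTCOME_CLASSES:
        raise ValidationError(
            f"unknown outcome class {outcome_class!r}; expected one of {OUTCOME_CLASSES}"
        )
    hr = 1.0 if outcome_class == "non_asd" else getattr(params, _CLASS_HR[outcome_class])
    if outcome_class == "non_asd":
        qol = QolSchedule(base_weight=1.0)
    else:
        qol = QolSchedule(
            base_weight=getattr(params, _CLASS_QOL[outcome_class]),
            decline_per_year=params.qol_decline_per_year,
            decline_start_age=params.qol_decline_start_age,
        )
    trace = cohort_trace(lt, hr, start_age)
    return MarkovPayoff(
        discounted_qalys=discounted_qalys(trace, qol, params.discount_rate),
        discounted_cost=discounted_costs(
            trace, params.annual_costs, outcome_class, perspective, params.discount_rate
        ),
        life_expectancy=life_expectancy(trace),
    )
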