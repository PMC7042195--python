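"""Synthetic inputs: a Gompertz–Makeham life table and random parameter scenarios.

The bundled life table is a deterministic synthetic emulation of a recent
U.S. both-sexes period life table — near-flat child mortality from a
Makeham background hazard, exponentially rising adult mortality from a
Gompertz term, and a terminal age with death probability 1.  It is not a
transcription of any federal table; its senescent baseline is calibrated
so remaining life expectancy at the model start age (6 y) equals the
73.2-year figure of the 2012 U.S. period table, inside the 70–75-year
window the engine assumes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy.optimize import brentq

from .markov import LifeTable, MODEL_START_AGE, cohort_trace, life_expectancy
from .parameters import ParameterSet, ValidationError, apply_override

__all__ = [
    "GompertzMakehamParams",
    "DEFAULT_GM_PARAMS",
    "LE6_TARGET",
    "LE6_WINDOW",
    "make_life_table",
    "bundled_life_table",
    "calibrate_senescent_hazard",
    "random_scenarios",
]


@dataclass(frozen=True)
class GompertzMakehamParams:
    """Hazard h(x) = lam + a * exp(b * x); annual death probabilities follow
    from integrating the hazard over each year of age."""

    lam: float  # age-independent background hazard, 1/year
    a: float  # senescent hazard at age 0, 1/year
    b: float  # senescence rate, 1/year
    terminal_age: int = 110

    def __post_init__(self) -> None:
        if self.lam < 0 or self.a < 0:
            raise ValidationError("hazard components must be non-negative")
        if self.a > 0 and self.b <= 0:
            raise ValidationError("senescence rate b must be positive when a > 0")
        if self.terminal_age < 100:
            raise ValidationError("terminal age must be at least 100")


#: calibration target: remaining life expectancy at age 6 (2012 U.S. value)
LE6_TARGET = 73.2
#: admissible window for the bundled fixture's remaining life expectancy at 6
LE6_WINDOW = (70.0, 75.0)

#: frozen defaults; ``a`` solved by bisection so the age-6 remaining life
#: expectancy equals LE6_TARGET given the background and senescence terms
DEFAULT_GM_PARAMS = GompertzMakehamParams(
    lam=4.0e-4,
    a=2.38719448942491e-05,
    b=0.0955,
    terminal_age=110,
)


def make_life_table(p: GompertzMakehamParams) -> LifeTable:
    """Life table from ages 0 to the terminal age under a Gompertz–Makeham hazard.

    q(x) = 1 - exp(-lam - (a/b) * exp(b*x) * (exp(b) - 1)); the terminal
    entry is forced to 1.
    """
    ages = np.arange(0, p.terminal_age + 1, dtype=float)
    if p.a == 0.0:
        cum = np.full_like(ages, p.lam)
    else:
        cum = p.lam + (p.a / p.b) * np.exp(p.b * ages) * (np.exp(p.b) - 1.0)
    q = 1.0 - np.exp(-cum)
    q[-1] = 1.0
    return LifeTable(start_age=0, q=q)


def bundled_life_table() -> LifeTable:
    """The deterministic built-in life-table fixture (synthetic emulation)."""
    return make_life_table(DEFAULT_GM_PARAMS)


def _remaining_le(lt: LifeTable, age: int) -> float:
    return life_expectancy(cohort_trace(lt, hr=1.0, start_age=age))


def calibrate_senescent_hazard(
    target_le: float = LE6_TARGET,
    at_age: int = MODEL_START_AGE,
    lam: float = DEFAULT_GM_PARAMS.lam,
    b: float = DEFAULT_GM_PARAMS.b,
    terminal_age: int = DEFAULT_GM_PARAMS.terminal_age,
) -> GompertzMakehamParams:
    """Solve (by bisection) for the senescent baseline hitting a life-expectancy target."""

    def objective(a: float) -> float:
        lt = make_life_table(GompertzMakehamParams(lam, a, b, terminal_age))
        return _remaining_le(lt, at_age) - target_le

    a = brentq(objective, 1e-10, 1e-2, xtol=1e-16)
    return GompertzMakehamParams(lam, float(a), b, terminal_age)


def random_scenarios(
    n: int,
    ranges: Mapping[str, tuple[float, float]],
    seed: int,
    base: ParameterSet | None = None,
) -> list[ParameterSet]:
    """Seeded uniform parameter scenarios for property sweeps.

    Each scenario draws every ranged parameter independently and uniformly
    within its (low, high) bounds; the with-ID utility weight is drawn
    conditionally below the without-ID draw so every scenario passes full
    validation.  Degenerate ranges reproduce their value exactly.
    """
    if n < 1:
        raise ValidationError("need n >= 1 scenarios")
    base = base if base is not None else ParameterSet()
    for name, (lo, hi) in ranges.items():
        if lo > hi:
            raise ValidationError(f"scenario range for {name!r} has low > high")
    rng = np.random.default_rng(seed)
    names = sorted(ranges)
    out = []
    for _ in range(n):
        p = base
        drawn: dict[str, float] = {}
        for name in names:
            lo, hi = ranges[name]
            if name == "qol_asd_id" and "qol_asd" in drawn:
                hi = min(hi, drawn["qol_asd"])
                lo = min(lo, hi)
            value = lo if lo == hi else float(rng.uniform(lo, hi))
            drawn[name] = value
            p = apply_override(p, name, value)
        out.append(p)
    return out
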