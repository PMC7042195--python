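"""The four-strategy screening decision tree.

Strategies: Status Quo (symptom-driven identification only), Test & Treat
at 6 or 12 months (MRI screen, early intervention for positives,
screen-negatives monitored as under the status quo), and Treat All (early
intervention for every high-risk sibling).  The tree resolves, per cohort
member, whether ASD is present, whether early intervention (EI) starts
before age 4, and — given ASD — whether intellectual disability (ID)
co-occurs.  EI lowers the ID risk by the configured risk ratio; false
positives incur the intervention cost but no other effect.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .parameters import ParameterSet, Perspective, ValidationError

__all__ = [
    "STRATEGY_LABELS",
    "Strategy",
    "default_strategies",
    "PathProbabilities",
    "TerminalMixture",
    "path_probabilities",
    "outcome_mixture",
    "relative_risk_id",
    "expected_upfront_cost",
    "mixture_table",
]

STRATEGY_LABELS = ("status_quo", "test_treat_6", "test_treat_12", "treat_all")

#: ages (years) at which the screening scan is performed, used only when
#: upfront costs are optionally discounted back to birth
_SCAN_AGE = {"test_treat_6": 0.5, "test_treat_12": 1.0}
#: nominal age of the early-intervention outlay under the same option
_EI_AGE = 3.0


@dataclass(frozen=True)
class Strategy:
    """A screening/treatment strategy; test strategies carry test characteristics."""

    label: str
    sensitivity: float | None = None
    specificity: float | None = None

    def __post_init__(self) -> None:
        if self.label not in STRATEGY_LABELS:
            raise ValidationError(
                f"unknown strategy {self.label!r}; expected one of {STRATEGY_LABELS}"
            )
        if self.is_test:
            if self.sensitivity is None or self.specificity is None:
                raise ValidationError(f"{self.label} requires sensitivity and specificity")
        elif self.sensitivity is not None or self.specificity is not None:
            raise ValidationError(f"{self.label} carries no test characteristics")

    @property
    def is_test(self) -> bool:
        return self.label in ("test_treat_6", "test_treat_12")

    @classmethod
    def from_label(cls, label: str, params: ParameterSet) -> "Strategy":
        if label == "test_treat_6":
            return cls(label, params.sens_mri_6, params.spec_mri_6)
        if label == "test_treat_12":
            return cls(label, params.sens_mri_12, params.spec_mri_12)
        return cls(label)


def default_strategies(params: ParameterSet) -> tuple[Strategy, ...]:
    """All four modelled strategies with test characteristics from ``params``."""
    return tuple(Strategy.from_label(label, params) for label in STRATEGY_LABELS)


@dataclass(frozen=True)
class PathProbabilities:
    """Terminal path probabilities of one strategy's subtree.

    Paths that a strategy cannot reach are zero; the nine fields always
    sum to one.
    """

    true_positive: float = 0.0
    false_negative_with_ei: float = 0.0
    false_negative_without_ei: float = 0.0
    false_positive: float = 0.0
    true_negative: float = 0.0
    asd_with_ei: float = 0.0
    asd_without_ei: float = 0.0
    non_asd_treated: float = 0.0
    non_asd_untreated: float = 0.0

    def as_dict(self) -> dict[str, float]:
        return {
            "true_positive": self.true_positive,
            "false_negative_with_ei": self.false_negative_with_ei,
            "false_negative_without_ei": self.false_negative_without_ei,
            "false_positive": self.false_positive,
            "true_negative": self.true_negative,
            "asd_with_ei": self.asd_with_ei,
            "asd_without_ei": self.asd_without_ei,
            "non_asd_treated": self.non_asd_treated,
            "non_asd_untreated": self.non_asd_untreated,
        }

    @property
    def asd_with_ei_total(self) -> float:
        """Cohort fraction with ASD that starts EI before age 4."""
        return self.true_positive + self.false_negative_with_ei + self.asd_with_ei

    @property
    def asd_without_ei_total(self) -> float:
        return self.false_negative_without_ei + self.asd_without_ei

    @property
    def received_ei(self) -> float:
        """Cohort fraction receiving EI (true/false positives included)."""
        return self.asd_with_ei_total + self.false_positive + self.non_asd_treated

    @property
    def total(self) -> float:
        return sum(self.as_dict().values())


@dataclass(frozen=True)
class TerminalMixture:
    """Cohort fractions over the three terminal outcome classes."""

    f_asd_id: float
    f_asd_only: float
    f_non_asd: float
    f_received_ei: float
    f_screened: float

    def fraction(self, outcome_class: str) -> float:
        return {
            "asd_id": self.f_asd_id,
            "asd_only": self.f_asd_only,
            "non_asd": self.f_non_asd,
        }[outcome_class]


def path_probabilities(strategy: Strategy, params: ParameterSet) -> PathProbabilities:
    """Resolve the chance nodes of one strategy into terminal path probabilities."""
    prev = params.prevalence_asd
    p_ei = params.p_early_intervention
    if strategy.label == "status_quo":
        return PathProbabilities(
            asd_with_ei=prev * p_ei,
            asd_without_ei=prev * (1.0 - p_ei),
            non_asd_untreated=1.0 - prev,
        )
    if strategy.label == "treat_all":
        return PathProbabilities(
            asd_with_ei=prev,
            non_asd_treated=1.0 - prev,
        )
    sens, spec = strategy.sensitivity, strategy.specificity
    # screen-negatives are monitored as under the status quo: they receive
    # EI before age 4 with probability p_early_intervention
    return PathProbabilities(
        true_positive=prev * sens,
        false_negative_with_ei=prev * (1.0 - sens) * p_ei,
        false_negative_without_ei=prev * (1.0 - sens) * (1.0 - p_ei),
        false_positive=(1.0 - prev) * (1.0 - spec),
        true_negative=(1.0 - prev) * spec,
    )


def outcome_mixture(strategy: Strategy, params: ParameterSet) -> TerminalMixture:
    """Aggregate path probabilities into terminal outcome-class fractions.

    Conditional ID risk is ``p_id_without_ei`` without early intervention
    and ``p_id_without_ei * rr_id_with_ei`` with it.
    """
    paths = path_probabilities(strategy, params)
    p_id = params.p_id_without_ei
    f_asd_id = (
        paths.asd_with_ei_total * p_id * params.rr_id_with_ei
        + paths.asd_without_ei_total * p_id
    )
    f_asd_only = params.prevalence_asd - f_asd_id
    return TerminalMixture(
        f_asd_id=f_asd_id,
        f_asd_only=f_asd_only,
        f_non_asd=1.0 - params.prevalence_asd,
        f_received_ei=paths.received_ei,
        f_screened=1.0 if strategy.is_test else 0.0,
    )


def relative_risk_id(
    strategy: Strategy, params: ParameterSet, baseline: Strategy
) -> float:
    """Relative risk of ID comorbidity, ``strategy`` over ``baseline``."""
    base = outcome_mixture(baseline, params).f_asd_id
    if base == 0.0:
        raise ValidationError(
            f"baseline strategy {baseline.label!r} has zero ID prevalence; relative risk undefined"
        )
    return outcome_mixture(strategy, params).f_asd_id / base


def expected_upfront_cost(
    strategy: Strategy, params: ParameterSet, perspective: Perspective
) -> float:
    """Expected pre-age-6 cost per cohort member (screening + early intervention).

    Undiscounted by default: these outlays precede the Markov cohort's
    start.  With ``discount_upfront_to_birth`` set, the MRI is discounted
    from the scan age and EI from a nominal age of 3.
    """
    mixture = outcome_mixture(strategy, params)
    mri_factor = 1.0
    ei_factor = 1.0
    if params.discount_upfront_to_birth and strategy.is_test:
        mri_factor = (1.0 + params.discount_rate) ** -_SCAN_AGE[strategy.label]
    if params.discount_upfront_to_birth:
        ei_factor = (1.0 + params.discount_rate) ** -_EI_AGE
    mri = mixture.f_screened * params.cost_mri * perspective.mri_share * mri_factor
    ei = mixture.f_received_ei * params.cost_ei * perspective.ei_share * ei_factor
    return mri + ei


def mixture_table(params: ParameterSet, strategies=None) -> pd.DataFrame:
    """Tidy (strategy, class, fraction) table of the terminal mixtures."""
    if strategies is None:
        strategies = default_strategies(params)
    rows = []
    for s in strategies:
        mix = outcome_mixture(s, params)
        for cls in ("asd_id", "asd_only", "non_asd"):
            rows.append({"strategy": s.label, "class": cls, "fraction": mix.fraction(cls)})
    return pd.DataFrame(rows)
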