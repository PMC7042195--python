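"""Model parameters: validation, configuration loading, and derivations.

This module houses the base-case parameter set of the screening model
(branch probabilities, test characteristics, mortality hazard ratios,
utility weights, costs, discount rate), the age-banded annual cost
schedule, the three cost-accounting perspectives, and the distribution
specifications used by the probabilistic sensitivity analysis.  It also
implements the small derivations the model rests on: beta/gamma moment
matching, the decomposition of a pooled utility weight into with/without
intellectual-disability weights, and the IQ-shift risk ratio.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import yaml
from scipy.stats import norm

__all__ = [
    "ConfigurationError",
    "ValidationError",
    "Perspective",
    "PERSPECTIVE_LABELS",
    "CostSchedule",
    "DistributionSpec",
    "ParameterSet",
    "RunSettings",
    "ModelConfig",
    "OUTCOME_CLASSES",
    "ONE_WAY_PARAMETERS",
    "load_config",
    "load_parameters",
    "default_config",
    "beta_from_moments",
    "gamma_from_moments",
    "decompose_qol_weights",
    "derive_id_risk_ratio",
    "apply_override",
    "sample_parameter_set",
    "sample_parameter_draws",
]


class ConfigurationError(ValueError):
    """A configuration document is malformed or carries unknown keys."""


class ValidationError(ValueError):
    """A parameter value violates its admissible range or an invariant."""


#: Terminal outcome classes of the decision tree.
OUTCOME_CLASSES = ("non_asd", "asd_only", "asd_id")

PERSPECTIVE_LABELS = ("societal", "health_care", "educational")


@dataclass(frozen=True)
class Perspective:
    """A cost-accounting perspective.

    ``annual_cost_fraction`` is the share of the societal annual ASD-related
    cost streams the perspective bears; ``mri_share`` and ``ei_share`` are
    the shares of the one-time screening and early-intervention costs.
    """

    label: str
    annual_cost_fraction: float = 1.0
    mri_share: float = 1.0
    ei_share: float = 1.0

    def __post_init__(self) -> None:
        if self.label not in PERSPECTIVE_LABELS:
            raise ValidationError(
                f"unknown perspective {self.label!r}; expected one of {PERSPECTIVE_LABELS}"
            )
        for name in ("annual_cost_fraction", "mri_share", "ei_share"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{self.label}.{name} must lie in [0, 1], got {v}")


#: Age bands of the annual cost schedule: (first age, last age inclusive).
AGE_BANDS = ((6, 17), (18, 21), (22, None))


@dataclass(frozen=True)
class CostSchedule:
    """Annual ASD-related costs (societal totals) by outcome class and age band.

    Band boundaries are 6–17, 18–21 and 22+ years; the non-ASD class incurs
    no ASD-related annual cost.  Costs are 2018 USD per person-year.
    """

    asd_only: tuple[float, float, float]
    asd_id: tuple[float, float, float]

    def __post_init__(self) -> None:
        for cls in ("asd_only", "asd_id"):
            bands = getattr(self, cls)
            if len(bands) != len(AGE_BANDS):
                raise ValidationError(f"{cls} must give one cost per age band")
            if any(c < 0 for c in bands):
                raise ValidationError(f"{cls} annual costs must be non-negative")

    def band_index(self, age: int) -> int:
        for i, (lo, hi) in enumerate(AGE_BANDS):
            if age >= lo and (hi is None or age <= hi):
                return i
        raise ValidationError(f"age {age} lies outside all cost bands (first band starts at 6)")

    def annual_cost(self, age: int, outcome_class: str) -> float:
        """Societal annual cost at ``age`` for an outcome class."""
        if outcome_class == "non_asd":
            return 0.0
        if outcome_class not in ("asd_only", "asd_id"):
            raise ValidationError(
                f"unknown outcome class {outcome_class!r}; expected one of {OUTCOME_CLASSES}"
            )
        return getattr(self, outcome_class)[self.band_index(age)]

    def costs_for_ages(self, ages: np.ndarray, outcome_class: str) -> np.ndarray:
        """Vectorised :meth:`annual_cost` over an integer age grid."""
        if outcome_class == "non_asd":
            return np.zeros(len(ages))
        bands = np.asarray(getattr(self, outcome_class), dtype=float)
        if np.any(ages < AGE_BANDS[0][0]):
            bad = int(np.min(ages))
            raise ValidationError(f"age {bad} lies outside all cost bands (first band starts at 6)")
        idx = np.select([ages <= 17, ages <= 21], [0, 1], default=2)
        return bands[idx]

    def scaled(self, outcome_class: str, factor: float) -> "CostSchedule":
        """Return a copy with one class's cost stream scaled by ``factor``."""
        if factor < 0:
            raise ValidationError("cost scale factor must be non-negative")
        new = {cls: getattr(self, cls) for cls in ("asd_only", "asd_id")}
        new[outcome_class] = tuple(c * factor for c in new[outcome_class])
        return CostSchedule(**new)


@dataclass(frozen=True)
class DistributionSpec:
    """A sampling distribution given by its family and first two moments."""

    family: str
    mean: float
    sd: float | None = None
    range_low: float | None = None
    range_high: float | None = None

    def __post_init__(self) -> None:
        if self.family not in ("beta", "gamma", "fixed"):
            raise ValidationError(f"unknown distribution family {self.family!r}")
        if self.family == "fixed":
            return
        if self.sd is None or self.sd <= 0:
            raise ValidationError(f"{self.family} distribution needs sd > 0")
        if self.family == "beta":
            beta_from_moments(self.mean, self.sd)  # feasibility check
        else:
            gamma_from_moments(self.mean, self.sd)

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.family == "fixed":
            return np.full(n, self.mean)
        if self.family == "beta":
            a, b = beta_from_moments(self.mean, self.sd)
            return rng.beta(a, b, n)
        shape, scale = gamma_from_moments(self.mean, self.sd)
        return rng.gamma(shape, scale, n)


_PROBABILITY_FIELDS = (
    "prevalence_asd",
    "sens_mri_6",
    "sens_mri_12",
    "spec_mri_6",
    "spec_mri_12",
    "p_early_intervention",
    "p_id_without_ei",
)
_UTILITY_FIELDS = ("qol_asd", "qol_asd_id")
_POSITIVE_FIELDS = ("rr_id_with_ei", "hr_asd", "hr_asd_id")
_COST_FIELDS = ("cost_mri", "cost_ei")


@dataclass(frozen=True)
class ParameterSet:
    """The full base-case parameter set of the screening model.

    One instance carries every scalar the decision tree and the Markov
    engine consume.  Instances are immutable; one-way sensitivity analysis
    derives modified copies through :func:`apply_override`.
    """

    prevalence_asd: float = 0.15
    sens_mri_6: float = 0.82
    sens_mri_12: float = 0.88
    spec_mri_6: float = 1.0
    spec_mri_12: float = 0.95
    p_early_intervention: float = 0.62
    p_id_without_ei: float = 0.37
    rr_id_with_ei: float = 0.61
    hr_asd: float = 2.18
    hr_asd_id: float = 5.78
    qol_asd: float = 0.68
    qol_asd_id: float = 0.46
    cost_mri: float = 1814.0
    cost_ei: float = 148367.0
    annual_costs: CostSchedule = field(
        default_factory=lambda: CostSchedule(
            asd_only=(58526.0, 69889.0, 54154.0),
            asd_id=(95983.0, 127718.0, 96247.0),
        )
    )
    discount_rate: float = 0.03
    qol_decline_per_year: float = 0.0
    qol_decline_start_age: int = 18
    discount_upfront_to_birth: bool = False
    #: set True on PSA-sampled instances, where the two utility weights are
    #: drawn independently and may cross (this is what produces the negative
    #: incremental QALYs seen in the probabilistic analysis)
    allow_qol_overlap: bool = False

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in _PROBABILITY_FIELDS:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1], got {v}")
        for name in _UTILITY_FIELDS:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1], got {v}")
        for name in _POSITIVE_FIELDS:
            v = getattr(self, name)
            if not v > 0:
                raise ValidationError(f"{name} must be positive, got {v}")
        for name in _COST_FIELDS:
            v = getattr(self, name)
            if v < 0:
                raise ValidationError(f"{name} must be non-negative, got {v}")
        if not 0.0 <= self.discount_rate <= 1.0:
            raise ValidationError(
                f"discount_rate must lie in [0, 1], got {self.discount_rate}"
            )
        if self.qol_decline_per_year < 0:
            raise ValidationError("qol_decline_per_year must be non-negative")
        if not self.allow_qol_overlap and self.qol_asd < self.qol_asd_id:
            raise ValidationError(
                "qol_asd must be >= qol_asd_id "
                f"(got {self.qol_asd} < {self.qol_asd_id})"
            )

    def replace(self, **changes: Any) -> "ParameterSet":
        return dataclasses.replace(self, **changes)


#: Parameter names recognised by one-way sensitivity analysis.  The two
#: ``annual_cost_scale_*`` pseudo-parameters scale an entire annual cost
#: stream (the ±25% variation of the cost schedule).
ONE_WAY_PARAMETERS = (
    "prevalence_asd",
    "sens_mri_6",
    "sens_mri_12",
    "spec_mri_6",
    "spec_mri_12",
    "p_early_intervention",
    "p_id_without_ei",
    "rr_id_with_ei",
    "hr_asd",
    "hr_asd_id",
    "qol_asd",
    "qol_asd_id",
    "cost_mri",
    "cost_ei",
    "annual_cost_scale_asd",
    "annual_cost_scale_asd_id",
    "discount_rate",
)


def apply_override(params: ParameterSet, name: str, value: float) -> ParameterSet:
    """Return a copy of ``params`` with a single named parameter replaced."""
    if name not in ONE_WAY_PARAMETERS:
        raise ValidationError(
            f"unknown parameter {name!r}; valid names: {', '.join(ONE_WAY_PARAMETERS)}"
        )
    if name == "annual_cost_scale_asd":
        return params.replace(annual_costs=params.annual_costs.scaled("asd_only", value))
    if name == "annual_cost_scale_asd_id":
        return params.replace(annual_costs=params.annual_costs.scaled("asd_id", value))
    return params.replace(**{name: value})


# ---------------------------------------------------------------------------
# derivations


def beta_from_moments(mean: float, sd: float) -> tuple[float, float]:
    """Shape parameters (a, b) of the beta distribution with given moments.

    Solves a/(a+b) = mean and ab/((a+b)^2 (a+b+1)) = sd^2.
    """
    if not 0.0 < mean < 1.0:
        raise ValidationError(f"beta mean must lie in (0, 1), got {mean}")
    var = sd * sd
    bound = mean * (1.0 - mean)
    if not 0.0 < var < bound:
        raise ValidationError(
            f"beta sd infeasible: need 0 < sd^2 < mean*(1-mean) = {bound:.6g}, got sd^2 = {var:.6g}"
        )
    nu = bound / var - 1.0
    return mean * nu, (1.0 - mean) * nu


def gamma_from_moments(mean: float, sd: float) -> tuple[float, float]:
    """(shape, scale) of the gamma distribution with given mean and sd."""
    if mean <= 0 or sd <= 0:
        raise ValidationError(f"gamma moments must be positive, got mean={mean}, sd={sd}")
    shape = (mean / sd) ** 2
    return shape, sd * sd / mean


def decompose_qol_weights(
    overall_mean: float, id_prevalence: float, id_decrement: float
) -> tuple[float, float]:
    """Split a pooled ASD utility weight into (without-ID, with-ID) weights.

    Solves the 2x2 linear system
    ``(1-p)*w_asd + p*w_asd_id = overall_mean`` and
    ``w_asd - w_asd_id = id_decrement`` at comorbid ID prevalence ``p``.
    """
    for name, v in (
        ("overall_mean", overall_mean),
        ("id_prevalence", id_prevalence),
        ("id_decrement", id_decrement),
    ):
        if not 0.0 <= v <= 1.0:
            raise ValidationError(f"{name} must lie in [0, 1], got {v}")
    w_asd = overall_mean + id_prevalence * id_decrement
    w_asd_id = overall_mean - (1.0 - id_prevalence) * id_decrement
    if not (0.0 <= w_asd <= 1.0 and 0.0 <= w_asd_id <= 1.0):
        raise ValidationError(
            f"decomposition leaves a weight outside [0, 1]: ({w_asd:.4f}, {w_asd_id:.4f})"
        )
    return w_asd, w_asd_id


def derive_id_risk_ratio(
    base_iq_mean: float, base_iq_sd: float, iq_gain: float, threshold: float = 70.0
) -> float:
    """Risk ratio of ID after an intervention-attributable IQ gain.

    The risk ratio is P(IQ + gain < threshold) / P(IQ < threshold) under a
    Gaussian base IQ distribution.  Informational: the pipeline uses the
    configured ``rr_id_with_ei`` value directly.
    """
    if base_iq_sd <= 0:
        raise ValidationError("base_iq_sd must be positive")
    denom = norm.cdf((threshold - base_iq_mean) / base_iq_sd)
    if denom == 0.0:
        raise ValidationError("baseline P(IQ < threshold) is zero; risk ratio undefined")
    num = norm.cdf((threshold - base_iq_mean - iq_gain) / base_iq_sd)
    return float(num / denom)


# ---------------------------------------------------------------------------
# PSA sampling

#: ParameterSet fields eligible for probabilistic sampling.  Test
#: characteristics and all costs are deliberately absent: they are held
#: fixed in the probabilistic analysis and varied only one-way.
SAMPLABLE_FIELDS = (
    "prevalence_asd",
    "p_early_intervention",
    "p_id_without_ei",
    "rr_id_with_ei",
    "hr_asd",
    "hr_asd_id",
    "qol_asd",
    "qol_asd_id",
)


def _substream(seed: int, name: str) -> np.random.Generator:
    """Deterministic per-parameter random stream.

    The stream is keyed by (master seed, sha256 of the parameter name), so
    adding or removing a parameter never perturbs the draws of the others.
    """
    key = int.from_bytes(hashlib.sha256(name.encode()).digest()[:8], "little")
    return np.random.default_rng(np.random.SeedSequence([int(seed), key]))


def sample_parameter_draws(
    specs: Mapping[str, DistributionSpec], n: int, seed: int
) -> dict[str, np.ndarray]:
    """Vectorised seeded draws: one array of length ``n`` per spec'd parameter."""
    if n < 1:
        raise ValidationError(f"number of draws must be >= 1, got {n}")
    for name, spec in specs.items():
        if name not in SAMPLABLE_FIELDS:
            raise ValidationError(
                f"parameter {name!r} is not samplable; samplable: {', '.join(SAMPLABLE_FIELDS)}"
            )
        if not isinstance(spec, DistributionSpec):
            raise ValidationError(f"spec for {name!r} is not a DistributionSpec")
    return {
        name: specs[name].sample(_substream(seed, name), n) for name in sorted(specs)
    }


def sample_parameter_set(
    base: ParameterSet, specs: Mapping[str, DistributionSpec], seed: int
) -> ParameterSet:
    """One seeded Monte Carlo draw of the parameter set.

    Parameters without a spec (or with a ``fixed`` spec) keep their base
    value.  The draw is validated with the utility-weight overlap allowed,
    matching the independent sampling of the two QOL weights.
    """
    draws = sample_parameter_draws(specs, 1, seed)
    changes: dict[str, Any] = {name: float(arr[0]) for name, arr in draws.items()}
    return base.replace(allow_qol_overlap=True, **changes)


# ---------------------------------------------------------------------------
# configuration loading


@dataclass(frozen=True)
class RunSettings:
    perspective: str = "societal"
    wtp: tuple[float, ...] = (50000.0, 100000.0)
    psa_n: int = 10000
    seed: int | None = None
    start_age: int = 6

    def __post_init__(self) -> None:
        if self.psa_n < 1:
            raise ValidationError("psa_n must be >= 1")
        if self.start_age < 0:
            raise ValidationError("start_age must be non-negative")


@dataclass(frozen=True)
class ModelConfig:
    """A fully resolved model configuration (defaults merged with overrides)."""

    parameters: ParameterSet
    perspectives: dict[str, Perspective]
    distributions: dict[str, DistributionSpec]
    ranges: dict[str, tuple[float, float]]
    run: RunSettings

    def perspective(self, label: str) -> Perspective:
        try:
            return self.perspectives[label]
        except KeyError:
            raise ValidationError(
                f"unknown perspective {label!r}; configured: {sorted(self.perspectives)}"
            ) from None

    def resolved_dict(self) -> dict[str, Any]:
        """Every parameter actually in force, as a plain document (for manifests/logs)."""
        p = self.parameters
        return {
            "parameters": {
                f.name: getattr(p, f.name)
                for f in dataclasses.fields(p)
                if f.name not in ("annual_costs", "allow_qol_overlap")
            },
            "cost_schedule": {
                cls: dict(zip(("ages_6_17", "ages_18_21", "ages_22_plus"), getattr(p.annual_costs, cls)))
                for cls in ("asd_only", "asd_id")
            },
            "perspectives": {
                label: dataclasses.asdict(persp) for label, persp in self.perspectives.items()
            },
            "distributions": {
                name: {k: v for k, v in dataclasses.asdict(spec).items() if v is not None}
                for name, spec in self.distributions.items()
            },
            "ranges": {k: list(v) for k, v in self.ranges.items()},
            "run": dataclasses.asdict(self.run),
        }


def _default_document() -> dict[str, Any]:
    text = resources.files("sibscreen").joinpath("data/default_config.yaml").read_text()
    return yaml.safe_load(text)


#: sections an override may legitimately empty out entirely
_CLEARABLE_SECTIONS = ("ranges", "distributions")


def _merge(defaults: Mapping[str, Any], override: Mapping[str, Any], path: str = "") -> dict[str, Any]:
    merged = dict(defaults)
    for key, value in override.items():
        where = f"{path}{key}"
        if key not in defaults:
            raise ConfigurationError(f"unknown configuration key {where!r}")
        if isinstance(defaults[key], Mapping) and isinstance(value, Mapping):
            if not path and key in _CLEARABLE_SECTIONS and len(value) == 0:
                merged[key] = {}
            else:
                merged[key] = _merge(defaults[key], value, where + ".")
        else:
            merged[key] = value
    return merged


def _build_config(doc: Mapping[str, Any]) -> ModelConfig:
    pdoc = dict(doc["parameters"])
    sched_doc = doc["cost_schedule"]

    def bands(cls: str) -> tuple[float, float, float]:
        d = sched_doc[cls]
        return (float(d["ages_6_17"]), float(d["ages_18_21"]), float(d["ages_22_plus"]))

    schedule = CostSchedule(asd_only=bands("asd_only"), asd_id=bands("asd_id"))
    try:
        params = ParameterSet(annual_costs=schedule, **pdoc)
    except TypeError as exc:  # unknown field slipped past merge of a flat dict
        raise ConfigurationError(str(exc)) from None

    perspectives = {
        label: Perspective(label=label, **spec) for label, spec in doc["perspectives"].items()
    }
    distributions = {
        name: DistributionSpec(**spec) for name, spec in (doc.get("distributions") or {}).items()
    }
    ranges: dict[str, tuple[float, float]] = {}
    for name, pair in (doc.get("ranges") or {}).items():
        if name not in ONE_WAY_PARAMETERS:
            raise ConfigurationError(f"unknown parameter {name!r} in ranges section")
        lo, hi = float(pair[0]), float(pair[1])
        if lo > hi:
            raise ConfigurationError(f"range for {name!r} has low > high")
        ranges[name] = (lo, hi)
    run_doc = dict(doc.get("run") or {})
    if "wtp" in run_doc and run_doc["wtp"] is not None:
        run_doc["wtp"] = tuple(float(w) for w in run_doc["wtp"])
    run = RunSettings(**run_doc)
    return ModelConfig(
        parameters=params,
        perspectives=perspectives,
        distributions=distributions,
        ranges=ranges,
        run=run,
    )


def load_config(source: str | Path | Mapping[str, Any] | None = None) -> ModelConfig:
    """Load a model configuration, merging ``source`` over the shipped defaults.

    ``source`` may be None (pure defaults), a mapping, or a path to a YAML
    or JSON document.  Omitted keys take their base-case defaults; unknown
    keys raise :class:`ConfigurationError` naming the key.
    """
    defaults = _default_document()
    if source is None:
        doc = defaults
    else:
        if isinstance(source, Mapping):
            override: Any = source
        else:
            with open(source) as fh:
                override = yaml.safe_load(fh)
        if override is None:
            override = {}
        if not isinstance(override, Mapping):
            raise ConfigurationError("configuration document must be a mapping")
        doc = _merge(defaults, override)
    return _build_config(doc)


def default_config() -> ModelConfig:
    """The shipped base-case configuration."""
    return load_config(None)


def load_parameters(source: str | Path | Mapping[str, Any] | None = None) -> ParameterSet:
    """Load and validate the parameter set from a configuration document."""
    return load_config(source).parameters
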