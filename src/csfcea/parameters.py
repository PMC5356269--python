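"""Model inputs: loading, validation, and access.

Every quantity that enters the decision model is a :class:`ParamValue`
carrying a base-case value, a low/high range used by deterministic and
probabilistic sensitivity analysis, and a ``kind`` that determines both its
validity constraints and the distribution family used when it is sampled.
The packaged defaults (``data/table1_defaults.yaml``) hold the published
base-case inputs; a user configuration (YAML or JSON) overrides any subset
of them.

Rates labelled "annual rate per 100,000" are stored exactly as published and
interpreted as instantaneous annual hazards (value / 100,000 per person-year).
This convention is confirmed by the published rate/probability pairs: a
discontinuation rate of 28,768 corresponds to the stated 25% annual
probability via ``1 - exp(-0.28768)``.
"""

from __future__ import annotations

import copy
import dataclasses
import importlib.resources
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import yaml

__all__ = [
    "ParamValue",
    "TestAccuracy",
    "CohortSettings",
    "AccuracyTable",
    "MortalityModel",
    "NaturalHistoryRates",
    "TreatmentModel",
    "CostModel",
    "UtilityModel",
    "AnalysisSettings",
    "ParameterSet",
    "ParameterLoadError",
    "default_parameters",
    "load_parameters",
    "validate_parameters",
    "iter_params",
    "get_param",
    "serialize_parameters",
]

_KINDS = {
    "probability",
    "annual_rate_per_100k",
    "hazard_ratio",
    "cost_usd",
    "utility_weight",
    "coefficient",
}


class ParameterLoadError(ValueError):
    """Raised when a configuration document cannot produce a valid ParameterSet."""


@dataclass
class ParamValue:
    """One model input: base case, sensitivity range, and current value.

    ``value`` is what the model actually reads; it equals ``base`` unless a
    sensitivity analysis or a probabilistic draw has perturbed it.
    """

    base: float
    low: float
    high: float
    kind: str = "coefficient"
    units: str = ""
    value: float = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.value is None:
            self.value = self.base
        if self.kind not in _KINDS:
            raise ParameterLoadError(f"unknown parameter kind {self.kind!r}")

    @property
    def fixed(self) -> bool:
        """True for structural constants (zero-width range): never sampled."""
        return self.low == self.high

    def violations(self, name: str) -> list[str]:
        out = []
        if not (self.low <= self.base <= self.high):
            out.append(f"{name}: range violated, requires low <= base <= high "
                       f"(got low={self.low}, base={self.base}, high={self.high})")
        vals = {"base": self.base, "low": self.low, "high": self.high, "value": self.value}
        for label, v in vals.items():
            if self.kind in ("probability", "utility_weight") and not (0.0 <= v <= 1.0):
                # memantine's annualized utility increment is a QALY-per-year
                # quantity but still lies in [0, 1], so one rule covers both
                out.append(f"{name}.{label}: {self.kind} must be in [0, 1], got {v}")
            if self.kind in ("annual_rate_per_100k", "cost_usd") and v < 0:
                out.append(f"{name}.{label}: {self.kind} must be >= 0, got {v}")
            if self.kind == "hazard_ratio" and v <= 0:
                out.append(f"{name}.{label}: hazard ratio must be > 0, got {v}")
        return out


@dataclass
class TestAccuracy:
    """Sensitivity/specificity pair of a diagnostic criterion."""

    sn: ParamValue
    sp: ParamValue


@dataclass
class CohortSettings:
    start_age: ParamValue
    mix_mild: ParamValue
    mix_moderate: ParamValue
    mix_severe: ParamValue
    proportion_diagnosed_referral: ParamValue
    referral_prevalence: ParamValue
    pretest_prevalence: ParamValue

    def severity_mix(self) -> tuple[float, float, float]:
        return (self.mix_mild.value, self.mix_moderate.value, self.mix_severe.value)


@dataclass
class AccuracyTable:
    mr: TestAccuracy
    combined: TestAccuracy
    bm_given_mr_negative: TestAccuracy
    memory_impairment: TestAccuracy


@dataclass
class MortalityModel:
    coeff_a: ParamValue
    coeff_b: ParamValue
    hr_mild: ParamValue
    hr_moderate: ParamValue
    hr_severe: ParamValue
    hr_nonad: ParamValue


@dataclass
class NaturalHistoryRates:
    mild_to_moderate: ParamValue
    mild_to_severe: ParamValue
    moderate_to_mild: ParamValue
    moderate_to_severe: ParamValue
    severe_to_mild: ParamValue
    severe_to_moderate: ParamValue
    ltcf_mild: ParamValue
    ltcf_moderate: ParamValue
    ltcf_severe: ParamValue
    ltcf_nonad: ParamValue


@dataclass
class TreatmentModel:
    donepezil_uptake: ParamValue
    memantine_uptake: ParamValue
    disc_donepezil_community: ParamValue
    disc_donepezil_ltcf: ParamValue
    disc_memantine: ParamValue
    reinit_donepezil: ParamValue
    reinit_memantine: ParamValue
    hr_mild_to_moderate: ParamValue
    hr_moderate_to_mild: ParamValue
    hr_community_to_ltcf: ParamValue
    hr_community_to_ltcf_memantine: ParamValue
    memantine_utility: ParamValue
    fp_benefit_fraction: ParamValue


@dataclass
class CostModel:
    baseline_coeff_a: ParamValue
    baseline_coeff_b: ParamValue
    baseline_cap: ParamValue
    community_nonad: ParamValue
    community_mild: ParamValue
    community_moderate: ParamValue
    community_severe: ParamValue
    ltcf_facility: ParamValue
    ltcf_nonad: ParamValue
    ltcf_mild: ParamValue
    ltcf_moderate: ParamValue
    ltcf_severe: ParamValue
    donepezil_annual: ParamValue
    memantine_annual: ParamValue
    death_under90: ParamValue
    death_over90: ParamValue
    biomarker_test: ParamValue


@dataclass
class UtilityModel:
    age_60_64: ParamValue
    age_65_69: ParamValue
    age_70_74: ParamValue
    age_75_79: ParamValue
    age_80_plus: ParamValue
    community_nonad: ParamValue
    community_mild: ParamValue
    community_moderate: ParamValue
    community_severe: ParamValue
    ltcf_nonad: ParamValue
    ltcf_mild: ParamValue
    ltcf_moderate: ParamValue
    ltcf_severe: ParamValue
    lumbar_puncture_toll: ParamValue

    def age_weight(self, age: float) -> float:
        """Stepwise age-band weight; <60 uses the 60-64 band, >=80 the >79 band."""
        if age < 65:
            return self.age_60_64.value
        if age < 70:
            return self.age_65_69.value
        if age < 75:
            return self.age_70_74.value
        if age < 80:
            return self.age_75_79.value
        return self.age_80_plus.value


@dataclass
class AnalysisSettings:
    discount_rate_annual: float = 0.03
    cycle_length_months: float = 1.0
    wtp_thresholds: list = field(default_factory=lambda: [50_000.0, 100_000.0])
    psa_draws: int = 10_000
    max_age: float = 120.0
    rng_seed: int = 0


@dataclass
class ParameterSet:
    cohort: CohortSettings
    accuracy: AccuracyTable
    mortality: MortalityModel
    rates: NaturalHistoryRates
    treatment: TreatmentModel
    costs: CostModel
    utilities: UtilityModel
    settings: AnalysisSettings

    def copy(self) -> "ParameterSet":
        return copy.deepcopy(self)


# ---------------------------------------------------------------------------
# construction from documents

def _build(cls, tree: dict, path: str):
    """Construct a ParamValue or AnalysisSettings leaf from a mapping."""
    if cls is ParamValue and isinstance(tree, (int, float)):
        raise ParameterLoadError(
            f"{path}: expected a mapping with base/low/high (bare numbers "
            f"are only accepted as overrides on top of defaults)")
    try:
        return cls(**(tree or {}))
    except TypeError as e:
        raise ParameterLoadError(f"{path}: {e}") from e


# dataclass field types are strings under `from __future__ import annotations`
_TYPEMAP = {
    "cohort": CohortSettings, "accuracy": AccuracyTable, "mortality": MortalityModel,
    "rates": NaturalHistoryRates, "treatment": TreatmentModel, "costs": CostModel,
    "utilities": UtilityModel, "settings": AnalysisSettings,
    "mr": TestAccuracy, "combined": TestAccuracy,
    "bm_given_mr_negative": TestAccuracy, "memory_impairment": TestAccuracy,
}


def _resolve_type(f: dataclasses.Field, owner) -> type:
    if f.name in _TYPEMAP and owner is ParameterSet or f.name in (
            "mr", "combined", "bm_given_mr_negative", "memory_impairment"):
        return _TYPEMAP[f.name]
    return ParamValue


def _build_tree(cls, tree: dict, path: str = ""):
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in (tree or {}):
            raise ParameterLoadError(f"missing required field {path}{f.name}")
        sub = tree[f.name]
        p = f"{path}{f.name}"
        subcls = _resolve_type(f, cls)
        if subcls in (CohortSettings, AccuracyTable, MortalityModel, NaturalHistoryRates,
                      TreatmentModel, CostModel, UtilityModel, TestAccuracy):
            kwargs[f.name] = _build_tree(subcls, sub, p + ".")
        elif subcls is AnalysisSettings:
            kwargs[f.name] = _build(AnalysisSettings, sub, p)
        else:
            kwargs[f.name] = _build(ParamValue, sub, p)
    return cls(**kwargs)


def _defaults_tree() -> dict:
    text = (importlib.resources.files("csfcea") / "data" / "table1_defaults.yaml").read_text()
    return yaml.safe_load(text)


def default_parameters() -> ParameterSet:
    """The packaged base-case parameter set."""
    return _build_tree(ParameterSet, _defaults_tree())


def _merge_overrides(base: dict, overrides: dict, path: str = "") -> None:
    for key, val in overrides.items():
        p = f"{path}{key}"
        if key not in base:
            raise ParameterLoadError(f"unknown parameter {p!r}")
        tgt = base[key]
        if isinstance(val, dict) and not _is_leaf(val):
            if not isinstance(tgt, dict):
                raise ParameterLoadError(f"{p}: type mismatch (mapping given)")
            _merge_overrides(tgt, val, p + ".")
        elif isinstance(val, dict):  # full leaf replacement
            tgt.update(val)
        elif isinstance(val, (int, float)) and not isinstance(val, bool):
            # scalar override: shift the base case, widen the range if needed
            tgt["base"] = val
            tgt["value"] = val
            tgt["low"] = min(tgt["low"], val)
            tgt["high"] = max(tgt["high"], val)
        else:
            raise ParameterLoadError(f"{p}: type mismatch, expected number or mapping, "
                                     f"got {type(val).__name__}")


def _is_leaf(d: dict) -> bool:
    return "base" in d or "value" in d


def load_parameters(source=None) -> ParameterSet:
    """Load a validated ParameterSet.

    Parameters
    ----------
    source
        ``None`` for the packaged base-case defaults, a path to a YAML/JSON
        document, or an already-parsed mapping. Omitted fields take the
        packaged base-case values; scalar leaves override the base value.

    Raises
    ------
    ParameterLoadError
        On unknown/mistyped fields or any invariant violation.
    """
    tree = _defaults_tree()
    if source is not None:
        if isinstance(source, (str, Path)):
            text = Path(source).read_text()
            overrides = yaml.safe_load(text) if not str(source).endswith(".json") \
                else json.loads(text)
        elif isinstance(source, dict):
            overrides = source
        else:
            raise ParameterLoadError(f"unsupported source type {type(source).__name__}")
        if overrides:
            if "settings" in overrides:
                tree["settings"] = {**tree["settings"], **overrides.pop("settings")}
            _merge_overrides(tree, overrides)
    ps = _build_tree(ParameterSet, tree)
    problems = validate_parameters(ps)
    if problems:
        raise ParameterLoadError("invalid parameters:\n  " + "\n  ".join(problems))
    return ps


# ---------------------------------------------------------------------------
# traversal and validation

def iter_params(ps: ParameterSet) -> Iterator[tuple[str, ParamValue]]:
    """Yield (dotted path, ParamValue) for every model input, in a stable order."""

    def walk(obj, path):
        for f in dataclasses.fields(obj):
            child = getattr(obj, f.name)
            if isinstance(child, ParamValue):
                yield f"{path}{f.name}", child
            elif dataclasses.is_dataclass(child) and not isinstance(child, AnalysisSettings):
                yield from walk(child, f"{path}{f.name}.")

    yield from walk(ps, "")


def get_param(ps: ParameterSet, path: str) -> ParamValue:
    obj = ps
    for part in path.split("."):
        try:
            obj = getattr(obj, part)
        except AttributeError:
            raise KeyError(f"unknown parameter {path!r}") from None
    if not isinstance(obj, ParamValue):
        raise KeyError(f"{path!r} is not a scalar parameter")
    return obj


def validate_parameters(ps: ParameterSet) -> list[str]:
    """Check every invariant; returns a list of human-readable violations."""
    out: list[str] = []
    for path, pv in iter_params(ps):
        out.extend(pv.violations(path))

    mix = sum(ps.cohort.severity_mix())
    if abs(mix - 1.0) > 1e-9:
        out.append(f"cohort severity mix: sums to {mix:.6g}, must sum to 1")

    # direction invariants apply to the base case; sensitivity-analysis
    # values may legitimately cross them (the published ranges do)
    m = ps.mortality
    if not (m.hr_severe.base > m.hr_moderate.base > m.hr_mild.base > 1.0):
        out.append("mortality hazard ratios must satisfy severe > moderate > mild > 1 "
                   f"(got {m.hr_severe.base}, {m.hr_moderate.base}, {m.hr_mild.base})")

    t = ps.treatment
    if not t.hr_mild_to_moderate.base < 1.0:
        out.append("treatment.hr_mild_to_moderate must be < 1 (treatment slows "
                   f"progression), got {t.hr_mild_to_moderate.base}")
    if not t.hr_moderate_to_mild.base > 1.0:
        out.append("treatment.hr_moderate_to_mild must be > 1 (treatment promotes "
                   f"regression), got {t.hr_moderate_to_mild.base}")

    c = ps.costs
    if not (c.community_severe.base > c.community_moderate.base > 0):
        out.append("community incremental costs must increase with severity")

    u = ps.utilities
    if not (u.community_mild.base > u.community_moderate.base > u.community_severe.base):
        out.append("community utility weights must decrease with severity")
    return out


# ---------------------------------------------------------------------------
# serialization

def serialize_parameters(ps: ParameterSet) -> dict:
    """Round-trippable plain mapping: load(serialize(ps)) reproduces every field."""

    def conv(obj):
        if isinstance(obj, ParamValue):
            return {"base": obj.base, "low": obj.low, "high": obj.high,
                    "kind": obj.kind, "units": obj.units, "value": obj.value}
        if isinstance(obj, AnalysisSettings):
            return dataclasses.asdict(obj)
        if dataclasses.is_dataclass(obj):
            return {f.name: conv(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
        return obj

    return conv(ps)
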