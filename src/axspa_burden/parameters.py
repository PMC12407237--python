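"""Model inputs: definition, loading, validation, and time/price rescaling.

Every input of the delayed-diagnosis cost model lives in a single validated
:class:`ParameterSet`: cohort demographics (onset age, sex mix), the diagnostic
delay, excess-mortality multipliers, the discount rate, unit costs and resource
frequencies for the three costing perspectives, the uncertainty distribution
attached to each uncertain input, and the national-extrapolation inputs.

Time-rescaling follows the constant-hazard (exponential) convention throughout:
a rate ``r`` over a horizon ``t`` becomes the probability ``1 - exp(-r t)``,
and a probability over one horizon is moved to another via the implied hazard.
Monetary values are restated to the model price year with a cost inflation
index (NHSCII-style year -> index table).
"""

from __future__ import annotations

import dataclasses
import io
import math
import os
import warnings
from dataclasses import dataclass, field
from typing import Any, Iterator, Mapping

import yaml

__all__ = [
    "SchemaError",
    "ValidationError",
    "DistributionSpec",
    "Comorbidity",
    "HealthcareInputs",
    "OopInputs",
    "ProductivityInputs",
    "ExtrapolationInputs",
    "ParameterSet",
    "load_parameters",
    "rate_to_probability",
    "rescale_probability",
    "inflate_cost",
    "read_inflation_index",
    "SYNTHETIC_NHSCII",
]

#: Cycle length is structural: four 3-month cycles per year, exactly.
CYCLE_LENGTH_YEARS = 0.25

#: Synthetic stand-in for an NHS Cost Inflation Index series (year -> index).
#: The values are plausible-looking but invented; a real series can be supplied
#: through :func:`read_inflation_index`.
SYNTHETIC_NHSCII: dict[int, float] = {
    2014: 100.0,
    2015: 101.1,
    2016: 102.2,
    2017: 104.0,
    2018: 106.1,
    2019: 108.5,
    2020: 112.3,
    2021: 115.0,
    2022: 121.8,
}


class SchemaError(ValueError):
    """A configuration document does not conform to the parameter schema."""


class ValidationError(ValueError):
    """A parameter set violates one or more invariants (all are listed)."""


# ---------------------------------------------------------------------------
# Distribution specifications (for probabilistic sensitivity analysis)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DistributionSpec:
    """Uncertainty attached to a single parameter.

    ``kind`` is one of ``beta`` (quantities bounded in [0, 1]), ``gamma``
    (nonnegative costs/counts), ``uniform``, or ``fixed``.  When a 95% CI
    ``(ci_low, ci_high)`` is available it drives the spread; otherwise the
    symmetric fraction ``pct_range`` (default +/-20%) is used.
    """

    kind: str
    mean: float
    ci_low: float | None = None
    ci_high: float | None = None
    pct_range: float = 0.20

    _KINDS = ("beta", "gamma", "uniform", "fixed")

    def validate(self, name: str = "<unnamed>") -> list[str]:
        errs: list[str] = []
        if self.kind not in self._KINDS:
            errs.append(f"{name}: unknown distribution kind {self.kind!r}")
            return errs
        has_ci = self.ci_low is not None or self.ci_high is not None
        if has_ci and (self.ci_low is None or self.ci_high is None):
            errs.append(f"{name}: both ci_low and ci_high must be given")
        elif has_ci and not (self.ci_low <= self.mean <= self.ci_high):
            errs.append(
                f"{name}: need ci_low <= mean <= ci_high, got "
                f"({self.ci_low}, {self.mean}, {self.ci_high})"
            )
        if self.pct_range <= 0:
            errs.append(f"{name}: pct_range must be > 0")
        if self.kind == "beta":
            if not (0.0 <= self.mean <= 1.0):
                errs.append(f"{name}: beta mean must lie in [0,1], got {self.mean}")
            if has_ci and self.ci_low is not None and self.ci_high is not None:
                if self.ci_low < 0 or self.ci_high > 1:
                    errs.append(f"{name}: beta CI must lie within [0,1]")
        if self.kind in ("gamma", "uniform") and self.mean < 0:
            errs.append(f"{name}: {self.kind} mean must be nonnegative")
        return errs

    def to_dict(self) -> dict[str, Any]:
        d: dict[str, Any] = {"kind": self.kind, "mean": self.mean}
        if self.ci_low is not None:
            d["ci_low"] = self.ci_low
            d["ci_high"] = self.ci_high
        if self.pct_range != 0.20:
            d["pct_range"] = self.pct_range
        return d

    @classmethod
    def from_dict(cls, d: Mapping[str, Any], name: str = "<unnamed>") -> "DistributionSpec":
        allowed = {"kind", "mean", "ci_low", "ci_high", "pct_range"}
        unknown = set(d) - allowed
        if unknown:
            raise SchemaError(f"distribution for {name}: unknown keys {sorted(unknown)}")
        try:
            return cls(**{k: d[k] for k in d})
        except TypeError as exc:  # missing kind/mean
            raise SchemaError(f"distribution for {name}: {exc}") from exc


# ---------------------------------------------------------------------------
# Nested input blocks
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Comorbidity:
    """A comorbidity accruing management cost on onset while undiagnosed."""

    onset_probability_per_cycle: float
    management_cost: float


@dataclass(frozen=True)
class HealthcareInputs:
    """NHS-perspective resource use per undiagnosed person-cycle."""

    gp_visits_per_cycle: float = 1.25
    gp_unit_cost: float = 39.23
    physio_visits_per_cycle: float = 1.5
    physio_unit_cost: float = 54.0
    comorbidities: dict[str, Comorbidity] = field(
        default_factory=lambda: {
            "depression": Comorbidity(0.004, 2228.0),
            "anxiety": Comorbidity(0.003, 1583.0),
            "cardiovascular": Comorbidity(0.002, 3239.0),
            "uveitis": Comorbidity(0.006, 782.0),
            "ibd": Comorbidity(0.002, 3000.0),
        }
    )


@dataclass(frozen=True)
class OopInputs:
    """Patient-perspective (out-of-pocket) inputs.

    OTC medication costs are monthly per item and capped twice: each item at
    the NHS prescription charge, and the annual sum at the prepayment
    certificate.  Travel is costed as a return taxi trip per practice visit.
    """

    otc_item_monthly_costs: dict[str, float] = field(
        default_factory=lambda: {
            "ibuprofen": 8.00,
            "paracetamol": 4.50,
            "co_codamol": 12.00,
            "topical_nsaid": 10.50,
        }
    )
    practitioner_visits_per_cycle: dict[str, float] = field(
        default_factory=lambda: {"chiropractor": 2.0, "osteopath": 2.0}
    )
    practitioner_fees: dict[str, float] = field(
        default_factory=lambda: {"chiropractor": 55.0, "osteopath": 48.0}
    )
    travel_distance_km: float = 4.0
    fare_per_trip_one_way: float = 12.50
    exercise_cost_per_cycle: float = 90.0
    prescription_cap_monthly: float = 9.35
    prepayment_cap_annual: float = 108.10


@dataclass(frozen=True)
class ProductivityInputs:
    """Societal-perspective productivity-loss inputs (human-capital costing).

    Work-loss terms (absenteeism, presenteeism, staff turnover) apply to the
    employed fraction and stop at ``retirement_age``; early-retirement and
    unpaid-care terms apply throughout.
    """

    employment_probability: float = 0.80
    hourly_wage: dict[str, float] = field(
        default_factory=lambda: {"male": 15.53, "female": 13.54}
    )
    absenteeism_hours_per_cycle: float = 32.0
    presenteeism_cost_per_cycle: float = 4800.0
    turnover_cost_per_cycle: float = 500.0
    early_retirement_probability: float = 0.03
    early_retirement_cost_per_cycle: float = 4000.0
    unpaid_care_probability: float = 0.15
    unpaid_care_cost_per_cycle: float = 600.0
    retirement_age: float = 66.0


@dataclass(frozen=True)
class ExtrapolationInputs:
    """Inputs for scaling per-person costs to national annual totals."""

    prevalence_low: float = 0.003
    prevalence_high: float = 0.012
    nass_population: float = 220_000.0
    uk_adult_population: float = 53_930_490.0
    undiagnosed_fraction: float = 0.8335


def _default_distribution_specs() -> dict[str, DistributionSpec]:
    """Distribution attached to every uncertain input (PSA defaults).

    Probabilities and proportions get beta distributions, costs/counts/wages
    gamma, each with a +/-20% spread unless a CI is stated.  Structural
    constants (cycle length, onset age, discount rate, policy caps,
    retirement age, populations) stay fixed and carry no spec.
    """
    specs: dict[str, DistributionSpec] = {
        "pct_male": DistributionSpec("beta", 0.64, 0.55, 0.72),
        "mean_time_to_diagnosis": DistributionSpec("gamma", 8.5),
        "smr_male": DistributionSpec("gamma", 1.630),
        "smr_female": DistributionSpec("gamma", 1.380),
        "healthcare_inputs.gp_visits_per_cycle": DistributionSpec("gamma", 1.25),
        "healthcare_inputs.gp_unit_cost": DistributionSpec("gamma", 39.23),
        "healthcare_inputs.physio_visits_per_cycle": DistributionSpec("gamma", 1.5),
        "healthcare_inputs.physio_unit_cost": DistributionSpec("gamma", 54.0),
        "oop_inputs.fare_per_trip_one_way": DistributionSpec("gamma", 12.50),
        "oop_inputs.exercise_cost_per_cycle": DistributionSpec("gamma", 90.0),
        "productivity_inputs.employment_probability": DistributionSpec("beta", 0.80),
        "productivity_inputs.absenteeism_hours_per_cycle": DistributionSpec("gamma", 32.0),
        "productivity_inputs.presenteeism_cost_per_cycle": DistributionSpec("gamma", 4800.0),
        "productivity_inputs.turnover_cost_per_cycle": DistributionSpec("gamma", 500.0),
        "productivity_inputs.early_retirement_probability": DistributionSpec("beta", 0.03),
        "productivity_inputs.early_retirement_cost_per_cycle": DistributionSpec("gamma", 4000.0),
        "productivity_inputs.unpaid_care_probability": DistributionSpec("beta", 0.15),
        "productivity_inputs.unpaid_care_cost_per_cycle": DistributionSpec("gamma", 600.0),
        "productivity_inputs.hourly_wage.male": DistributionSpec("gamma", 15.53),
        "productivity_inputs.hourly_wage.female": DistributionSpec("gamma", 13.54),
    }
    for name, com in HealthcareInputs().comorbidities.items():
        specs[f"healthcare_inputs.comorbidities.{name}.onset_probability_per_cycle"] = (
            DistributionSpec("beta", com.onset_probability_per_cycle)
        )
        specs[f"healthcare_inputs.comorbidities.{name}.management_cost"] = (
            DistributionSpec("gamma", com.management_cost)
        )
    for name, fee in OopInputs().practitioner_fees.items():
        specs[f"oop_inputs.practitioner_fees.{name}"] = DistributionSpec("gamma", fee)
    for name, v in OopInputs().practitioner_visits_per_cycle.items():
        specs[f"oop_inputs.practitioner_visits_per_cycle.{name}"] = DistributionSpec("gamma", v)
    for name, c in OopInputs().otc_item_monthly_costs.items():
        specs[f"oop_inputs.otc_item_monthly_costs.{name}"] = DistributionSpec("gamma", c)
    return specs


# ---------------------------------------------------------------------------
# The parameter set
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ParameterSet:
    """Every model input, validated as a unit.

    Defaults are the base-case study conditions: symptom onset at 26 years,
    64% male, a mean diagnostic delay of 8.5 years against a 1-year gold
    standard, sex-specific standardized mortality ratios of 1.630 (male) and
    1.380 (female), and 3.5% annual discounting at 2021 prices.  Unit-cost and
    resource-frequency defaults without a published point value are synthetic
    (see the synthetic-data module, which documents the plausible ranges).
    """

    onset_age: float = 26.0
    pct_male: float = 0.64
    mean_time_to_diagnosis: float = 8.5
    gold_standard_ttd: float = 1.0
    smr_male: float = 1.630
    smr_female: float = 1.380
    # No published point estimates in the main text; synthetic, overridable.
    diagnostic_sensitivity: float = 0.79
    diagnostic_specificity: float = 0.72
    discount_rate_annual: float = 0.035
    cycle_length: float = CYCLE_LENGTH_YEARS
    price_year: int = 2021
    healthcare_inputs: HealthcareInputs = field(default_factory=HealthcareInputs)
    oop_inputs: OopInputs = field(default_factory=OopInputs)
    productivity_inputs: ProductivityInputs = field(default_factory=ProductivityInputs)
    extrapolation_inputs: ExtrapolationInputs = field(default_factory=ExtrapolationInputs)
    distribution_specs: dict[str, DistributionSpec] = field(
        default_factory=_default_distribution_specs
    )
    provenance: dict[str, str] = field(default_factory=dict)

    # -- validation ---------------------------------------------------------

    def validate(self) -> "ParameterSet":
        """Check every invariant; raise :class:`ValidationError` listing all
        failures, warn (without failing) on an SMR below 1."""
        errs: list[str] = []

        def prop(name: str, v: float) -> None:
            if not (0.0 <= v <= 1.0):
                errs.append(f"{name} must lie in [0,1], got {v}")

        def nonneg(name: str, v: float) -> None:
            if v < 0:
                errs.append(f"{name} must be >= 0, got {v}")

        prop("pct_male", self.pct_male)
        prop("diagnostic_sensitivity", self.diagnostic_sensitivity)
        prop("diagnostic_specificity", self.diagnostic_specificity)
        prop("discount_rate_annual", self.discount_rate_annual)
        if self.onset_age < 0:
            errs.append(f"onset_age must be >= 0, got {self.onset_age}")
        if abs(self.cycle_length * 4 - 1.0) > 0:
            errs.append(f"cycle_length must be exactly 0.25 years, got {self.cycle_length}")
        if self.mean_time_to_diagnosis <= 0:
            errs.append("mean_time_to_diagnosis must be > 0")
        if self.gold_standard_ttd <= 0:
            errs.append("gold_standard_ttd must be > 0")
        if self.mean_time_to_diagnosis < self.gold_standard_ttd:
            errs.append(
                "mean_time_to_diagnosis must be >= gold_standard_ttd "
                f"({self.mean_time_to_diagnosis} < {self.gold_standard_ttd})"
            )
        for name, smr in (("smr_male", self.smr_male), ("smr_female", self.smr_female)):
            if smr <= 0:
                errs.append(f"{name} must be > 0, got {smr}")
            elif smr < 1:
                warnings.warn(
                    f"{name} = {smr} < 1 implies below-population mortality",
                    UserWarning,
                    stacklevel=2,
                )

        hc = self.healthcare_inputs
        nonneg("healthcare_inputs.gp_visits_per_cycle", hc.gp_visits_per_cycle)
        nonneg("healthcare_inputs.gp_unit_cost", hc.gp_unit_cost)
        nonneg("healthcare_inputs.physio_visits_per_cycle", hc.physio_visits_per_cycle)
        nonneg("healthcare_inputs.physio_unit_cost", hc.physio_unit_cost)
        for name, com in hc.comorbidities.items():
            prop(
                f"healthcare_inputs.comorbidities.{name}.onset_probability_per_cycle",
                com.onset_probability_per_cycle,
            )
            nonneg(f"healthcare_inputs.comorbidities.{name}.management_cost", com.management_cost)

        oop = self.oop_inputs
        for name, v in oop.otc_item_monthly_costs.items():
            nonneg(f"oop_inputs.otc_item_monthly_costs.{name}", v)
        for name, v in oop.practitioner_visits_per_cycle.items():
            nonneg(f"oop_inputs.practitioner_visits_per_cycle.{name}", v)
        for name, v in oop.practitioner_fees.items():
            nonneg(f"oop_inputs.practitioner_fees.{name}", v)
        if set(oop.practitioner_visits_per_cycle) != set(oop.practitioner_fees):
            errs.append("practitioner_visits_per_cycle and practitioner_fees must share keys")
        nonneg("oop_inputs.travel_distance_km", oop.travel_distance_km)
        nonneg("oop_inputs.fare_per_trip_one_way", oop.fare_per_trip_one_way)
        nonneg("oop_inputs.exercise_cost_per_cycle", oop.exercise_cost_per_cycle)
        nonneg("oop_inputs.prescription_cap_monthly", oop.prescription_cap_monthly)
        nonneg("oop_inputs.prepayment_cap_annual", oop.prepayment_cap_annual)

        pr = self.productivity_inputs
        prop("productivity_inputs.employment_probability", pr.employment_probability)
        prop("productivity_inputs.early_retirement_probability", pr.early_retirement_probability)
        prop("productivity_inputs.unpaid_care_probability", pr.unpaid_care_probability)
        for sex in ("male", "female"):
            if sex not in pr.hourly_wage:
                errs.append(f"productivity_inputs.hourly_wage missing {sex!r}")
            else:
                nonneg(f"productivity_inputs.hourly_wage.{sex}", pr.hourly_wage[sex])
        nonneg("productivity_inputs.absenteeism_hours_per_cycle", pr.absenteeism_hours_per_cycle)
        nonneg("productivity_inputs.presenteeism_cost_per_cycle", pr.presenteeism_cost_per_cycle)
        nonneg("productivity_inputs.turnover_cost_per_cycle", pr.turnover_cost_per_cycle)
        nonneg(
            "productivity_inputs.early_retirement_cost_per_cycle",
            pr.early_retirement_cost_per_cycle,
        )
        nonneg("productivity_inputs.unpaid_care_cost_per_cycle", pr.unpaid_care_cost_per_cycle)
        if pr.retirement_age <= self.onset_age:
            errs.append("retirement_age must exceed onset_age")

        ex = self.extrapolation_inputs
        prop("extrapolation_inputs.prevalence_low", ex.prevalence_low)
        prop("extrapolation_inputs.prevalence_high", ex.prevalence_high)
        prop("extrapolation_inputs.undiagnosed_fraction", ex.undiagnosed_fraction)
        nonneg("extrapolation_inputs.nass_population", ex.nass_population)
        nonneg("extrapolation_inputs.uk_adult_population", ex.uk_adult_population)

        for name, spec in self.distribution_specs.items():
            errs.extend(spec.validate(name))
            try:
                self.get(name)
            except KeyError:
                errs.append(f"distribution_specs names unknown parameter {name!r}")

        if errs:
            raise ValidationError("; ".join(errs))
        return self

    # -- dotted-path access -------------------------------------------------

    def get(self, path: str) -> Any:
        """Resolve a dotted parameter path, e.g.
        ``'oop_inputs.practitioner_fees.osteopath'``."""
        obj: Any = self
        for part in path.split("."):
            if isinstance(obj, Mapping):
                if part not in obj:
                    raise KeyError(path)
                obj = obj[part]
            elif dataclasses.is_dataclass(obj) and part in {
                f.name for f in dataclasses.fields(obj)
            }:
                obj = getattr(obj, part)
            else:
                raise KeyError(path)
        return obj

    def updated(self, overrides: Mapping[str, Any]) -> "ParameterSet":
        """Return a new validated set with dotted-path overrides applied."""
        d = self.to_dict()
        for path, value in overrides.items():
            node = d
            parts = path.split(".")
            while len(parts) > 1:
                # dict-valued blocks (e.g. distribution_specs) key on full
                # dotted names, so prefer a literal match on the remainder
                remainder = ".".join(parts)
                if isinstance(node, Mapping) and remainder in node:
                    parts = [remainder]
                    break
                if parts[0] not in node:
                    raise KeyError(path)
                node = node[parts[0]]
                parts = parts[1:]
            if parts[0] not in node:
                raise KeyError(path)
            node[parts[0]] = value
        return ParameterSet.from_dict(d).validate()

    # -- (de)serialization --------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["distribution_specs"] = {k: v.to_dict() for k, v in self.distribution_specs.items()}
        return d

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "ParameterSet":
        def build(dc_type: type, mapping: Mapping[str, Any], ctx: str) -> Any:
            names = {f.name for f in dataclasses.fields(dc_type)}
            unknown = set(mapping) - names
            if unknown:
                raise SchemaError(f"{ctx}: unknown key(s) {sorted(unknown)}")
            return dc_type(**dict(mapping))

        allowed = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - allowed
        if unknown:
            raise SchemaError(f"parameter set: unknown key(s) {sorted(unknown)}")
        kw: dict[str, Any] = dict(d)
        if "healthcare_inputs" in kw and isinstance(kw["healthcare_inputs"], Mapping):
            hc = dict(kw["healthcare_inputs"])
            if "comorbidities" in hc:
                hc["comorbidities"] = {
                    name: build(Comorbidity, c, f"comorbidities.{name}")
                    if isinstance(c, Mapping)
                    else c
                    for name, c in hc["comorbidities"].items()
                }
            kw["healthcare_inputs"] = build(HealthcareInputs, hc, "healthcare_inputs")
        for key, typ in (
            ("oop_inputs", OopInputs),
            ("productivity_inputs", ProductivityInputs),
            ("extrapolation_inputs", ExtrapolationInputs),
        ):
            if key in kw and isinstance(kw[key], Mapping):
                kw[key] = build(typ, kw[key], key)
        if "distribution_specs" in kw:
            kw["distribution_specs"] = {
                name: DistributionSpec.from_dict(s, name) if isinstance(s, Mapping) else s
                for name, s in kw["distribution_specs"].items()
            }
        return cls(**kw)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True, default_flow_style=False)


# ---------------------------------------------------------------------------
# Loading
# ---------------------------------------------------------------------------


def _strip_metadata(
    node: Any, path: str, specs: dict[str, Any], prov: dict[str, str]
) -> Any:
    """Collapse ``{value, provenance, distribution}`` leaves to plain values,
    collecting distribution specs and provenance tags keyed by dotted path."""
    if isinstance(node, Mapping):
        if "value" in node:
            allowed = {"value", "provenance", "distribution"}
            unknown = set(node) - allowed
            if unknown:
                raise SchemaError(f"{path}: unknown key(s) {sorted(unknown)}")
            if "provenance" in node:
                if node["provenance"] not in ("paper", "synthetic", "user"):
                    raise SchemaError(f"{path}: bad provenance {node['provenance']!r}")
                prov[path] = node["provenance"]
            if "distribution" in node:
                specs[path] = node["distribution"]
            return node["value"]
        return {
            key: _strip_metadata(sub, f"{path}.{key}" if path else str(key), specs, prov)
            for key, sub in node.items()
        }
    return node


def load_parameters(config_source: Any = None) -> ParameterSet:
    """Load and validate a parameter configuration.

    ``config_source`` may be ``None`` / an empty document (pure defaults), a
    YAML string, a path to a YAML file, an open text stream, or an
    already-parsed mapping.  Leaves may be plain scalars or mappings with
    ``{value, provenance, distribution}`` metadata.  Unknown keys are
    rejected with a :class:`SchemaError` naming the offending key; invariant
    violations raise a :class:`ValidationError` listing every failure.
    """
    if config_source is None:
        doc: Any = {}
    elif isinstance(config_source, Mapping):
        doc = dict(config_source)
    elif isinstance(config_source, io.IOBase) or hasattr(config_source, "read"):
        doc = yaml.safe_load(config_source.read())
    elif isinstance(config_source, (str, os.PathLike)):
        text = str(config_source)
        if isinstance(config_source, os.PathLike) or (
            "\n" not in text and (text.endswith((".yml", ".yaml")) or os.path.exists(text))
        ):
            with open(config_source, "r", encoding="utf-8") as fh:
                doc = yaml.safe_load(fh.read())
        else:
            doc = yaml.safe_load(text)
    else:
        raise SchemaError(f"unsupported configuration source {type(config_source)!r}")
    if doc is None:
        doc = {}
    if not isinstance(doc, Mapping):
        raise SchemaError("configuration document must be a mapping")

    inline_specs: dict[str, Any] = {}
    prov: dict[str, str] = {}
    plain = _strip_metadata(dict(doc), "", inline_specs, prov)

    defaults = ParameterSet().to_dict()
    merged = _deep_merge(defaults, plain)
    if inline_specs:
        spec_block = dict(merged.get("distribution_specs", {}))
        spec_block.update(inline_specs)
        merged["distribution_specs"] = spec_block
    if prov:
        merged["provenance"] = {**merged.get("provenance", {}), **prov}
    return ParameterSet.from_dict(merged).validate()


def _deep_merge(base: Mapping[str, Any], override: Mapping[str, Any]) -> dict[str, Any]:
    out = dict(base)
    for key, value in override.items():
        if key in out and isinstance(out[key], Mapping) and isinstance(value, Mapping):
            out[key] = _deep_merge(out[key], value)
        else:
            out[key] = value
    return out


# ---------------------------------------------------------------------------
# Rate / probability / price rescaling
# ---------------------------------------------------------------------------


def rate_to_probability(rate: float, horizon: float) -> float:
    """Convert an event rate (per year) to a probability over ``horizon``
    years under a constant hazard: ``1 - exp(-rate * horizon)``."""
    if rate < 0:
        raise ValueError(f"rate must be >= 0, got {rate}")
    if horizon <= 0:
        raise ValueError(f"horizon must be > 0, got {horizon}")
    return -math.expm1(-rate * horizon)


def rescale_probability(p: float, t1: float, t2: float) -> float:
    """Move a probability from horizon ``t1`` to ``t2`` (years) under a
    constant hazard: ``1 - (1 - p) ** (t2 / t1)``."""
    if t1 <= 0 or t2 <= 0:
        raise ValueError("horizons must be > 0")
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"probability must lie in [0,1], got {p}")
    if p == 1.0:
        if t2 < t1:
            raise ValueError("cannot rescale a certain event to a shorter horizon")
        return 1.0
    return -math.expm1((t2 / t1) * math.log1p(-p))


def inflate_cost(
    cost: float, from_year: int, index: Mapping[int, float], price_year: int = 2021
) -> float:
    """Restate ``cost`` from ``from_year`` prices to ``price_year`` prices
    using an inflation index table (year -> index value)."""
    for year in (from_year, price_year):
        if year not in index:
            raise LookupError(f"year {year} missing from inflation index")
    return cost * index[price_year] / index[from_year]


def read_inflation_index(source: Any) -> dict[int, float]:
    """Read a two-column ``year,index`` CSV (header required) into a dict."""
    import pandas as pd

    df = pd.read_csv(source)
    if list(df.columns[:2]) != ["year", "index"]:
        raise SchemaError("inflation index file must have columns 'year,index'")
    return {int(y): float(v) for y, v in zip(df["year"], df["index"])}
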