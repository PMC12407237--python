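"""Synthetic model inputs: parameter sets and a UK-like life table.

No public deposit exists for the model's full input tables (unit costs,
resource frequencies, employment inputs, comorbidity probabilities, the
background life table), so this module generates internally consistent
synthetic stand-ins.  Two kinds of value are kept strictly apart:

* published constants (onset age 26, 64% male, 8.5-year mean delay,
  SMRs 1.630/1.380, 3.5% discounting, the prescription caps, prevalences and
  populations) are emitted verbatim and tagged ``provenance: paper``;
* everything else is drawn from the documented plausible ranges in
  :data:`SYNTHETIC_RANGES` and tagged ``provenance: synthetic``.

The default scenario is the package's base-case study condition; the stress
scenario pushes every synthetic unit cost and frequency to the top of its
range.  Background mortality uses a Gompertz–Makeham hazard
``mu(age) = a + b * exp(c * age)`` with sex-specific coefficients drawn in
UK-plausible ranges (male mortality kept above female by construction).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping

import numpy as np

from .mortality import SEXES, LifeTable
from .parameters import DistributionSpec, ParameterSet

__all__ = [
    "SyntheticScenario",
    "SYNTHETIC_RANGES",
    "PUBLISHED_CONSTANTS",
    "generate_life_table",
    "generate_parameter_set",
]

#: Published point values, fixed in every generated scenario.
PUBLISHED_CONSTANTS: dict[str, float] = {
    "onset_age": 26.0,
    "pct_male": 0.64,
    "mean_time_to_diagnosis": 8.5,
    "gold_standard_ttd": 1.0,
    "smr_male": 1.630,
    "smr_female": 1.380,
    "discount_rate_annual": 0.035,
    "cycle_length": 0.25,
    "oop_inputs.prescription_cap_monthly": 9.35,
    "oop_inputs.prepayment_cap_annual": 108.10,
    "extrapolation_inputs.prevalence_low": 0.003,
    "extrapolation_inputs.prevalence_high": 0.012,
    "extrapolation_inputs.nass_population": 220_000.0,
    "extrapolation_inputs.uk_adult_population": 53_930_490.0,
    "extrapolation_inputs.undiagnosed_fraction": 0.8335,
}

#: Plausible (low, high) ranges for every synthetic input, dotted by path.
#: Defaults in :class:`~axspa_burden.parameters.ParameterSet` sit at the
#: midpoints; the default scenario draws uniformly inside the range, the
#: stress scenario takes the upper bound.
SYNTHETIC_RANGES: dict[str, tuple[float, float]] = {
    "diagnostic_sensitivity": (0.75, 0.83),
    "diagnostic_specificity": (0.68, 0.76),
    "healthcare_inputs.gp_visits_per_cycle": (1.125, 1.375),
    "healthcare_inputs.gp_unit_cost": (35.31, 43.15),
    "healthcare_inputs.physio_visits_per_cycle": (1.35, 1.65),
    "healthcare_inputs.physio_unit_cost": (48.6, 59.4),
    "healthcare_inputs.comorbidities.depression.onset_probability_per_cycle": (0.0036, 0.0044),
    "healthcare_inputs.comorbidities.depression.management_cost": (2005.2, 2450.8),
    "healthcare_inputs.comorbidities.anxiety.onset_probability_per_cycle": (0.0027, 0.0033),
    "healthcare_inputs.comorbidities.anxiety.management_cost": (1424.7, 1741.3),
    "healthcare_inputs.comorbidities.cardiovascular.onset_probability_per_cycle": (0.0018, 0.0022),
    "healthcare_inputs.comorbidities.cardiovascular.management_cost": (2915.1, 3562.9),
    "healthcare_inputs.comorbidities.uveitis.onset_probability_per_cycle": (0.0054, 0.0066),
    "healthcare_inputs.comorbidities.uveitis.management_cost": (703.8, 860.2),
    "healthcare_inputs.comorbidities.ibd.onset_probability_per_cycle": (0.0018, 0.0022),
    "healthcare_inputs.comorbidities.ibd.management_cost": (2700.0, 3300.0),
    "oop_inputs.otc_item_monthly_costs.ibuprofen": (7.2, 8.8),
    "oop_inputs.otc_item_monthly_costs.paracetamol": (4.05, 4.95),
    "oop_inputs.otc_item_monthly_costs.co_codamol": (10.8, 13.2),
    "oop_inputs.otc_item_monthly_costs.topical_nsaid": (9.45, 11.55),
    "oop_inputs.practitioner_visits_per_cycle.chiropractor": (1.8, 2.2),
    "oop_inputs.practitioner_visits_per_cycle.osteopath": (1.8, 2.2),
    "oop_inputs.practitioner_fees.chiropractor": (49.5, 60.5),
    "oop_inputs.practitioner_fees.osteopath": (43.2, 52.8),
    "oop_inputs.travel_distance_km": (3.6, 4.4),
    "oop_inputs.fare_per_trip_one_way": (11.25, 13.75),
    "oop_inputs.exercise_cost_per_cycle": (81.0, 99.0),
    "productivity_inputs.employment_probability": (0.76, 0.84),
    "productivity_inputs.hourly_wage.male": (13.98, 17.08),
    "productivity_inputs.hourly_wage.female": (12.19, 14.89),
    "productivity_inputs.absenteeism_hours_per_cycle": (28.8, 35.2),
    "productivity_inputs.presenteeism_cost_per_cycle": (4320.0, 5280.0),
    "productivity_inputs.turnover_cost_per_cycle": (450.0, 550.0),
    "productivity_inputs.early_retirement_probability": (0.027, 0.033),
    "productivity_inputs.early_retirement_cost_per_cycle": (3600.0, 4400.0),
    "productivity_inputs.unpaid_care_probability": (0.135, 0.165),
    "productivity_inputs.unpaid_care_cost_per_cycle": (540.0, 660.0),
}

#: Paths treated as proportions (beta distribution in the PSA).
_PROPORTION_PATHS = {
    path
    for path in SYNTHETIC_RANGES
    if "probability" in path or path.startswith("diagnostic_")
}


@dataclass(frozen=True)
class SyntheticScenario:
    """A reproducible synthetic study condition."""

    seed: int = 0
    scale: str = "default"  # or "stress"
    overrides: dict[str, Any] = field(default_factory=dict)

    def validate(self) -> "SyntheticScenario":
        if self.scale not in ("default", "stress"):
            raise ValueError(f"scale must be 'default' or 'stress', got {self.scale!r}")
        return self


def generate_life_table(seed: int, max_age: int = 100) -> LifeTable:
    """Generate a UK-plausible Gompertz–Makeham life table.

    Female coefficients are drawn first; male mortality is obtained by
    scaling the female background and senescent terms up, which enforces
    male qx >= female qx at every age.  The table is closed with qx = 1 at
    ``max_age``.
    """
    if max_age < 100:
        raise ValueError(f"max_age must be >= 100, got {max_age}")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x11FE]))
    a_f = rng.uniform(5e-5, 2e-4)
    b_f = rng.uniform(1.5e-5, 4e-5)
    c = rng.uniform(0.095, 0.105)
    a_m = a_f * rng.uniform(1.3, 1.8)
    b_m = b_f * rng.uniform(1.2, 1.6)
    ages = np.arange(0, max_age + 1, dtype=float)
    qx: dict[str, np.ndarray] = {}
    for sex, (a, b) in (("male", (a_m, b_m)), ("female", (a_f, b_f))):
        hazard = a + b * np.exp(c * ages)
        q = -np.expm1(-hazard)
        q[-1] = 1.0
        qx[sex] = q
    return LifeTable(min_age=0, max_age=max_age, qx=qx).validate()


def _spec_for(path: str, value: float) -> DistributionSpec:
    """Uncertainty spec for a generated value: beta for proportions, gamma
    otherwise, +/-20% spread; the sex mix keeps its published CI."""
    if path == "pct_male":
        return DistributionSpec("beta", value, 0.55, 0.72)
    if path in _PROPORTION_PATHS or path == "pct_male":
        return DistributionSpec("beta", value)
    return DistributionSpec("gamma", value)


def generate_parameter_set(scenario: SyntheticScenario | None = None) -> ParameterSet:
    """Emit a complete, validated parameter set for a synthetic scenario.

    Published constants are fixed; synthetic inputs are drawn uniformly
    within :data:`SYNTHETIC_RANGES` (upper bounds under the stress scale).
    Every uncertain input gets a distribution spec centred on its emitted
    value; scenario overrides are applied last and re-validated.
    """
    scenario = (scenario or SyntheticScenario()).validate()
    rng = np.random.default_rng(np.random.SeedSequence([scenario.seed, 0x5EED]))
    values: dict[str, float] = dict(PUBLISHED_CONSTANTS)
    provenance = {path: "paper" for path in PUBLISHED_CONSTANTS}
    for path, (lo, hi) in SYNTHETIC_RANGES.items():
        u = float(rng.uniform(lo, hi))  # drawn even under stress, for stream parity
        values[path] = hi if scenario.scale == "stress" else u
        provenance[path] = "synthetic"

    specs: dict[str, DistributionSpec] = {
        "pct_male": _spec_for("pct_male", values["pct_male"]),
        "mean_time_to_diagnosis": DistributionSpec("gamma", values["mean_time_to_diagnosis"]),
        "smr_male": DistributionSpec("gamma", values["smr_male"]),
        "smr_female": DistributionSpec("gamma", values["smr_female"]),
    }
    # inert or purely informational inputs carry no PSA spread
    no_spread = {
        "diagnostic_sensitivity",
        "diagnostic_specificity",
        "oop_inputs.travel_distance_km",
    }
    for path in SYNTHETIC_RANGES:
        if path not in no_spread:
            specs[path] = _spec_for(path, values[path])

    overrides = dict(scenario.overrides)
    base = ParameterSet.from_dict(
        {"distribution_specs": {k: v.to_dict() for k, v in specs.items()},
         "provenance": provenance}
    )
    params = base.updated(values)
    if overrides:
        params = params.updated(overrides)
        # keep the spec means in step with overridden values where one exists
        respec = {
            f"distribution_specs.{path}": DistributionSpec(
                params.distribution_specs[path].kind,
                float(value),
                params.distribution_specs[path].ci_low,
                params.distribution_specs[path].ci_high,
                params.distribution_specs[path].pct_range,
            ).to_dict()
            for path, value in overrides.items()
            if path in params.distribution_specs
        }
        if respec:
            params = params.updated(respec)
    return params.validate()
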