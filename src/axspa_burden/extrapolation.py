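"""National extrapolation of per-person costs under prevalence scenarios.

The per-person annual cost of diagnostic delay is scaled to the UK patient
population three ways: the patient-society estimate of the prevalent
population (220 000), and prevalence applied to the UK adult population at
the conservative (0.3%, ASAS criteria) and broad (1.2%, ESSG criteria)
estimates.  Only the fraction of the prevalent population still undiagnosed
in a given year accrues delay costs.
"""

from __future__ import annotations

from dataclasses import dataclass

from .parameters import ParameterSet

__all__ = [
    "NationalEstimate",
    "population_from_prevalence",
    "national_cost",
    "build_scenarios",
]


@dataclass(frozen=True)
class NationalEstimate:
    """One national-scenario row: population x undiagnosed fraction x
    per-person annual cost."""

    scenario_name: str
    population: float
    undiagnosed_fraction: float
    per_person_annual_cost: float

    @property
    def total_annual_cost(self) -> float:
        return self.per_person_annual_cost * self.population * self.undiagnosed_fraction

    def validate(self) -> "NationalEstimate":
        if min(self.population, self.undiagnosed_fraction, self.per_person_annual_cost) < 0:
            raise ValueError("all national-estimate fields must be >= 0")
        if self.undiagnosed_fraction > 1:
            raise ValueError("undiagnosed_fraction must be <= 1")
        return self


def population_from_prevalence(adult_population: float, prevalence: float) -> float:
    """Prevalent patient count implied by a population prevalence
    (fractional persons permitted; rounding happens only at render time)."""
    if not (0.0 <= prevalence <= 1.0):
        raise ValueError(f"prevalence must lie in [0,1], got {prevalence}")
    if adult_population < 0:
        raise ValueError("adult_population must be >= 0")
    return adult_population * prevalence


def national_cost(
    per_person_annual_cost: float, population: float, undiagnosed_fraction: float
) -> float:
    """Total national annual cost: the triple product."""
    if min(per_person_annual_cost, population, undiagnosed_fraction) < 0:
        raise ValueError("inputs must be >= 0")
    if undiagnosed_fraction > 1:
        raise ValueError("undiagnosed_fraction must be <= 1")
    return per_person_annual_cost * population * undiagnosed_fraction


def build_scenarios(params: ParameterSet, per_person_annual_cost: float) -> list[NationalEstimate]:
    """The three standard national scenarios for a given per-person annual
    cost: patient-society population, low prevalence, high prevalence."""
    ex = params.extrapolation_inputs
    frac = ex.undiagnosed_fraction
    scenarios = [
        NationalEstimate("nass_population", ex.nass_population, frac, per_person_annual_cost),
        NationalEstimate(
            "prevalence_0.3pct",
            population_from_prevalence(ex.uk_adult_population, ex.prevalence_low),
            frac,
            per_person_annual_cost,
        ),
        NationalEstimate(
            "prevalence_1.2pct",
            population_from_prevalence(ex.uk_adult_population, ex.prevalence_high),
            frac,
            per_person_annual_cost,
        ),
    ]
    return [s.validate() for s in scenarios]
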