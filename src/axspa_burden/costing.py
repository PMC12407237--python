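"""Cost accrual over the cohort trace, across three perspectives.

Costs attach only to the UNDIAGNOSED state (the model quantifies the burden
of the diagnostic delay; once diagnosed, people leave the costed pathway)
and are discounted to cycle 0 at the annual rate, compounded by cycle.
Three perspectives are accrued separately:

* healthcare — NHS-perspective formal care (GP, physiotherapy, comorbidity
  management);
* out_of_pocket — patient-perspective spend (capped OTC medication,
  chiropractor/osteopath fees, return taxi travel to practices,
  non-prescribed exercise);
* productivity — societal-perspective losses valued at the gross wage
  (absenteeism, presenteeism, staff turnover, early retirement, unpaid care).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .cohort import CohortTrace, MarkovState
from .parameters import ParameterSet

__all__ = [
    "CostBreakdown",
    "discount_factor",
    "otc_capped_cost",
    "healthcare_cycle_cost",
    "oop_cycle_cost",
    "productivity_cycle_cost",
    "accumulate_costs",
]

CATEGORIES = ("healthcare", "out_of_pocket", "productivity")


@dataclass(frozen=True)
class CostBreakdown:
    """Discounted per-cycle and cumulative costs by category.

    All arrays are aligned with the trace's cycle grid; totals are the last
    entries of the cumulative series.
    """

    cycle_index: np.ndarray
    attained_age: np.ndarray
    per_cycle: dict[str, np.ndarray]  # category -> discounted per-cycle cost

    @property
    def per_cycle_total(self) -> np.ndarray:
        return sum(self.per_cycle[c] for c in CATEGORIES)

    def cumulative(self, category: str) -> np.ndarray:
        if category == "total":
            return np.cumsum(self.per_cycle_total)
        return np.cumsum(self.per_cycle[category])

    def total(self, category: str = "total") -> float:
        return float(self.cumulative(category)[-1])

    def totals(self) -> dict[str, float]:
        out = {c: self.total(c) for c in CATEGORIES}
        out["total"] = self.total("total")
        return out

    def validate(self, rtol: float = 1e-9) -> "CostBreakdown":
        for c in CATEGORIES:
            if np.any(self.per_cycle[c] < 0):
                raise ValueError(f"{c} per-cycle costs must be >= 0")
        tot = self.total("total")
        parts = sum(self.total(c) for c in CATEGORIES)
        if tot > 0 and abs(tot - parts) > rtol * tot:
            raise ValueError("total must equal the sum of the categories")
        return self

    @staticmethod
    def mix(a: "CostBreakdown", b: "CostBreakdown", weight_a: float) -> "CostBreakdown":
        """Convex combination of two breakdowns on identical cycle grids."""
        if len(a.cycle_index) != len(b.cycle_index):
            raise ValueError("breakdowns are on different cycle grids")
        w = weight_a
        return CostBreakdown(
            cycle_index=a.cycle_index.copy(),
            attained_age=a.attained_age.copy(),
            per_cycle={c: w * a.per_cycle[c] + (1 - w) * b.per_cycle[c] for c in CATEGORIES},
        )

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame({"cycle": self.cycle_index, "age": self.attained_age})
        for c in CATEGORIES:
            df[c] = self.per_cycle[c]
            df[f"cumulative_{c}"] = self.cumulative(c)
        df["total"] = self.per_cycle_total
        df["cumulative_total"] = self.cumulative("total")
        return df


def discount_factor(cycle_index, discount_rate_annual: float, cycle_length: float):
    """Present-value multiplier ``(1 + r)^(-cycle_index * cycle_length)``."""
    idx = np.asarray(cycle_index)
    if np.any(idx < 0):
        raise ValueError("cycle_index must be >= 0")
    out = (1.0 + discount_rate_annual) ** (-idx * cycle_length)
    return float(out) if np.isscalar(cycle_index) else out


def otc_capped_cost(
    item_monthly_costs: Iterable[float],
    prescription_cap_monthly: float = 9.35,
    prepayment_cap_annual: float = 108.10,
) -> float:
    """Annual per-person OTC medication cost under the NHS caps.

    Each item's monthly cost is capped at the prescription charge (a patient
    buying several medicines can get them on prescription instead); the
    annualized sum is further capped at the prepayment certificate.
    """
    items = list(item_monthly_costs)
    if any(c < 0 for c in items):
        raise ValueError("OTC item costs must be >= 0")
    if prescription_cap_monthly < 0 or prepayment_cap_annual < 0:
        raise ValueError("caps must be >= 0")
    monthly = sum(min(c, prescription_cap_monthly) for c in items)
    return min(12.0 * monthly, prepayment_cap_annual)


def healthcare_cycle_cost(params: ParameterSet) -> float:
    """NHS-perspective cost per undiagnosed person-cycle."""
    hc = params.healthcare_inputs
    cost = hc.gp_visits_per_cycle * hc.gp_unit_cost
    cost += hc.physio_visits_per_cycle * hc.physio_unit_cost
    for com in hc.comorbidities.values():
        cost += com.onset_probability_per_cycle * com.management_cost
    return cost


def oop_cycle_cost(params: ParameterSet) -> float:
    """Out-of-pocket cost per undiagnosed person-cycle.

    Travel counts a return taxi trip (2 x one-way fare) for every practice
    visit: GP, physiotherapy, and each out-of-pocket practitioner.
    """
    oop = params.oop_inputs
    hc = params.healthcare_inputs
    otc_annual = otc_capped_cost(
        oop.otc_item_monthly_costs.values(),
        oop.prescription_cap_monthly,
        oop.prepayment_cap_annual,
    )
    cost = otc_annual / 4.0  # annual cap spread evenly over the 4 cycles
    for name, visits in oop.practitioner_visits_per_cycle.items():
        cost += visits * oop.practitioner_fees[name]
    trips = (
        hc.gp_visits_per_cycle
        + hc.physio_visits_per_cycle
        + sum(oop.practitioner_visits_per_cycle.values())
    )
    cost += trips * 2.0 * oop.fare_per_trip_one_way
    cost += oop.exercise_cost_per_cycle
    return cost


def productivity_cycle_cost(params: ParameterSet, sex: str, attained_age: float) -> float:
    """Societal productivity loss per undiagnosed person-cycle.

    Work-loss terms apply to the employed fraction and are valued at the
    sex-specific gross median hourly wage; they stop at the retirement age.
    Early-retirement and unpaid-care terms persist at any age.
    """
    pr = params.productivity_inputs
    if sex not in pr.hourly_wage:
        raise KeyError(f"no wage for sex {sex!r}")
    cost = (
        pr.early_retirement_probability * pr.early_retirement_cost_per_cycle
        + pr.unpaid_care_probability * pr.unpaid_care_cost_per_cycle
    )
    if attained_age < pr.retirement_age:
        wage = pr.hourly_wage[sex]
        cost += pr.employment_probability * (
            pr.absenteeism_hours_per_cycle * wage
            + pr.presenteeism_cost_per_cycle
            + pr.turnover_cost_per_cycle
        )
    return cost


def accumulate_costs(trace: CohortTrace, params: ParameterSet, sex: str) -> CostBreakdown:
    """Accrue discounted category costs over the trace.

    Per cycle: category cost x UNDIAGNOSED occupancy at cycle start x
    discount factor.  DIAGNOSED and DEAD accrue nothing.
    """
    occ_u = trace.occupancy[:, MarkovState.UNDIAGNOSED]
    disc = discount_factor(trace.cycle_index, params.discount_rate_annual, params.cycle_length)
    hc = healthcare_cycle_cost(params)
    oop = oop_cycle_cost(params)
    prod = np.array(
        [productivity_cycle_cost(params, sex, age) for age in trace.attained_age]
    )
    per_cycle = {
        "healthcare": hc * occ_u * disc,
        "out_of_pocket": oop * occ_u * disc,
        "productivity": prod * occ_u * disc,
    }
    return CostBreakdown(
        cycle_index=trace.cycle_index.copy(),
        attained_age=trace.attained_age.copy(),
        per_cycle=per_cycle,
    ).validate()
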