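"""Cost accrual: discounting, caps, per-cycle ledgers, accumulation."""

import numpy as np
import pytest

from axspa_burden import (
    accumulate_costs,
    discount_factor,
    healthcare_cycle_cost,
    oop_cycle_cost,
    otc_capped_cost,
    productivity_cycle_cost,
    run_cohort,
)
from axspa_burden.cohort import CohortTrace
from axspa_burden.costing import CATEGORIES, CostBreakdown


class TestDiscountFactor:
    def test_cycle_zero(self):
        assert discount_factor(0, 0.035, 0.25) == 1.0

    def test_two_year_closed_form(self):
        assert discount_factor(8, 0.035, 0.25) == pytest.approx(0.933510700366403, abs=1e-12)

    def test_zero_rate_always_one(self):
        np.testing.assert_array_equal(discount_factor(np.arange(50), 0.0, 0.25), 1.0)

    def test_negative_cycle_rejected(self):
        with pytest.raises(ValueError):
            discount_factor(-1, 0.035, 0.25)


class TestOtcCap:
    def test_both_caps_bind(self):
        # £25/month item -> £9.35 monthly cap -> £112.20 -> £108.10 annual cap
        assert otc_capped_cost([25.0]) == pytest.approx(108.10)

    def test_no_cap_binds(self):
        assert otc_capped_cost([5.0]) == pytest.approx(60.0)

    def test_empty_list(self):
        assert otc_capped_cost([]) == 0.0

    def test_per_item_cap_applies_before_summing(self):
        # two expensive items: 2 * 9.35 * 12 = 224.40, then annual cap
        assert otc_capped_cost([50.0, 50.0]) == pytest.approx(108.10)

    def test_negative_cost_rejected(self):
        with pytest.raises(ValueError):
            otc_capped_cost([-1.0])


class TestCycleCosts:
    def test_zero_parameter_set_costs_nothing(self, params):
        zeroed = {
            "healthcare_inputs.gp_visits_per_cycle": 0.0,
            "healthcare_inputs.physio_visits_per_cycle": 0.0,
            "oop_inputs.exercise_cost_per_cycle": 0.0,
            "oop_inputs.fare_per_trip_one_way": 0.0,
            "productivity_inputs.employment_probability": 0.0,
            "productivity_inputs.early_retirement_probability": 0.0,
            "productivity_inputs.unpaid_care_probability": 0.0,
        }
        for name in params.healthcare_inputs.comorbidities:
            zeroed[f"healthcare_inputs.comorbidities.{name}.onset_probability_per_cycle"] = 0.0
        for name in params.oop_inputs.practitioner_visits_per_cycle:
            zeroed[f"oop_inputs.practitioner_visits_per_cycle.{name}"] = 0.0
        for name in params.oop_inputs.otc_item_monthly_costs:
            zeroed[f"oop_inputs.otc_item_monthly_costs.{name}"] = 0.0
        p = params.updated(zeroed)
        assert healthcare_cycle_cost(p) == 0.0
        assert oop_cycle_cost(p) == 0.0
        assert productivity_cycle_cost(p, "male", 30.0) == 0.0

    def test_healthcare_ledger_matches_hand_sum(self, params):
        """Independently itemized brute-force sum of the same inputs."""
        hc = params.healthcare_inputs
        ledger = hc.gp_visits_per_cycle * hc.gp_unit_cost
        ledger += hc.physio_visits_per_cycle * hc.physio_unit_cost
        for com in hc.comorbidities.values():
            ledger += com.onset_probability_per_cycle * com.management_cost
        assert healthcare_cycle_cost(params) == pytest.approx(ledger, rel=1e-12)

    def test_oop_ledger_matches_hand_sum(self, params):
        oop, hc = params.oop_inputs, params.healthcare_inputs
        monthly = sum(min(c, 9.35) for c in oop.otc_item_monthly_costs.values())
        ledger = min(12 * monthly, 108.10) / 4
        for name, v in oop.practitioner_visits_per_cycle.items():
            ledger += v * oop.practitioner_fees[name]
        trips = (
            hc.gp_visits_per_cycle
            + hc.physio_visits_per_cycle
            + sum(oop.practitioner_visits_per_cycle.values())
        )
        ledger += trips * 2 * oop.fare_per_trip_one_way
        ledger += oop.exercise_cost_per_cycle
        assert oop_cycle_cost(params) == pytest.approx(ledger, rel=1e-12)

    def test_single_visit_single_fare(self, params):
        p = params.updated(
            {
                "oop_inputs.practitioner_visits_per_cycle.osteopath": 1.0,
                "oop_inputs.practitioner_fees.osteopath": 50.0,
                "oop_inputs.fare_per_trip_one_way": 10.0,
            }
        )
        delta = oop_cycle_cost(p) - oop_cycle_cost(
            p.updated(
                {
                    "oop_inputs.practitioner_visits_per_cycle.osteopath": 0.0,
                }
            )
        )
        # one visit adds the fee plus a return trip: 50 + 2*10
        assert delta == pytest.approx(70.0, rel=1e-12)

    def test_absenteeism_term(self, params):
        base = {
            "productivity_inputs.presenteeism_cost_per_cycle": 0.0,
            "productivity_inputs.turnover_cost_per_cycle": 0.0,
            "productivity_inputs.early_retirement_probability": 0.0,
            "productivity_inputs.unpaid_care_probability": 0.0,
            "productivity_inputs.employment_probability": 1.0,
            "productivity_inputs.absenteeism_hours_per_cycle": 8.0,
            "productivity_inputs.hourly_wage.male": 15.0,
        }
        p = params.updated(base)
        assert productivity_cycle_cost(p, "male", 30.0) == pytest.approx(120.0)

    def test_wage_monotonicity_between_sexes(self, params):
        male = productivity_cycle_cost(params, "male", 30.0)
        female = productivity_cycle_cost(params, "female", 30.0)
        wages = params.productivity_inputs.hourly_wage
        assert (male > female) == (wages["male"] > wages["female"])

    def test_past_retirement_only_residual_terms(self, params):
        pr = params.productivity_inputs
        residual = (
            pr.early_retirement_probability * pr.early_retirement_cost_per_cycle
            + pr.unpaid_care_probability * pr.unpaid_care_cost_per_cycle
        )
        assert productivity_cycle_cost(params, "male", 70.0) == pytest.approx(residual)


class TestAccumulateCosts:
    def test_additivity(self, params, trace_male):
        bd = accumulate_costs(trace_male, params, "male")
        parts = sum(bd.total(c) for c in CATEGORIES)
        assert bd.total("total") == pytest.approx(parts, rel=1e-9)

    def test_cumulative_nondecreasing(self, params, trace_male):
        bd = accumulate_costs(trace_male, params, "male")
        for c in CATEGORIES + ("total",):
            assert np.all(np.diff(bd.cumulative(c)) >= -1e-12)

    def test_discount_monotonicity(self, params, trace_male):
        totals = [
            accumulate_costs(
                trace_male, params.updated({"discount_rate_annual": r}), "male"
            ).total("total")
            for r in (0.0, 0.015, 0.035, 0.06)
        ]
        assert all(a >= b for a, b in zip(totals, totals[1:]))

    def test_linearity_in_unit_costs(self, params, trace_male):
        k = 3.0
        scaled_paths = {}
        for name in params.healthcare_inputs.comorbidities:
            scaled_paths[f"healthcare_inputs.comorbidities.{name}.management_cost"] = (
                params.get(f"healthcare_inputs.comorbidities.{name}.management_cost") * k
            )
        for path in (
            "healthcare_inputs.gp_unit_cost",
            "healthcare_inputs.physio_unit_cost",
            "oop_inputs.fare_per_trip_one_way",
            "oop_inputs.exercise_cost_per_cycle",
            "oop_inputs.prescription_cap_monthly",
            "oop_inputs.prepayment_cap_annual",
            "productivity_inputs.presenteeism_cost_per_cycle",
            "productivity_inputs.turnover_cost_per_cycle",
            "productivity_inputs.early_retirement_cost_per_cycle",
            "productivity_inputs.unpaid_care_cost_per_cycle",
            "productivity_inputs.hourly_wage.male",
            "productivity_inputs.hourly_wage.female",
        ):
            scaled_paths[path] = params.get(path) * k
        for name in params.oop_inputs.otc_item_monthly_costs:
            scaled_paths[f"oop_inputs.otc_item_monthly_costs.{name}"] = (
                params.get(f"oop_inputs.otc_item_monthly_costs.{name}") * k
            )
        for name in params.oop_inputs.practitioner_fees:
            scaled_paths[f"oop_inputs.practitioner_fees.{name}"] = (
                params.get(f"oop_inputs.practitioner_fees.{name}") * k
            )
        scaled = params.updated(scaled_paths)
        base = accumulate_costs(trace_male, params, "male")
        big = accumulate_costs(trace_male, scaled, "male")
        for c in CATEGORIES + ("total",):
            assert big.total(c) == pytest.approx(k * base.total(c), rel=1e-12)

    def test_geometric_series_closed_form(self, params, no_mortality_table):
        """Constant per-cycle cost c, geometric hazard p, no death, no
        discounting: the cumulative total tends to c * E[undiagnosed cycles]
        = c / p."""
        p0 = params.updated({"discount_rate_annual": 0.0})
        trace = run_cohort(p0, no_mortality_table, "male")
        bd = accumulate_costs(trace, p0, "male")
        p_diag = 1 - np.exp(-0.25 / p0.mean_time_to_diagnosis)
        c = bd.per_cycle_total[0]  # cycle-0 cost at full occupancy
        # retirement cuts productivity later on, so compare a constant-cost variant
        const = p0.updated({"productivity_inputs.retirement_age": 1e6})
        bd_const = accumulate_costs(run_cohort(const, no_mortality_table, "male"), const, "male")
        c_const = bd_const.per_cycle_total[0]
        truncation = (1 - p_diag) ** (trace.n_cycles - 1)
        assert bd_const.total("total") == pytest.approx(
            c_const / p_diag * (1 - truncation), rel=1e-6
        )

    def test_only_undiagnosed_occupancy_accrues(self, params, trace_male):
        dead_after_first = CohortTrace(
            cycle_index=np.arange(3),
            attained_age=np.array([26.0, 26.25, 26.5]),
            occupancy=np.array([[1, 0, 0], [0, 0.5, 0.5], [0, 0, 1.0]]),
            newly_diagnosed=np.array([0.0, 0.5, 0.0]),
        )
        bd = accumulate_costs(dead_after_first, params, "male")
        assert bd.per_cycle_total[1:].sum() == 0.0
        assert bd.per_cycle_total[0] > 0.0

    def test_mix_is_convex_combination(self, params, trace_male, trace_female):
        a = accumulate_costs(trace_male, params, "male")
        b = accumulate_costs(trace_female, params, "female")
        mixed = CostBreakdown.mix(a, b, 0.64)
        for c in CATEGORIES + ("total",):
            assert mixed.total(c) == pytest.approx(
                0.64 * a.total(c) + 0.36 * b.total(c), rel=1e-9
            )
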