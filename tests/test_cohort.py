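"""Markov cohort engine: calibration, transitions, traces, mixing."""

import math

import numpy as np
import pytest

from axspa_burden import (
    MarkovState,
    calibrate_diagnosis_probability,
    mean_time_to_diagnosis,
    mix_cohorts,
    run_cohort,
    transition_matrix,
)
from axspa_burden.cohort import CohortTrace


class TestCalibration:
    def test_continuous_closed_form(self):
        p = calibrate_diagnosis_probability(8.5, 0.25, "continuous")
        assert p == pytest.approx(0.028983448207562823, abs=1e-15)

    def test_geometric_closed_form(self):
        p = calibrate_diagnosis_probability(8.5, 0.25, "geometric")
        assert p == pytest.approx(0.25 / 8.5, abs=1e-15)

    def test_geometric_boundary_rejected(self):
        with pytest.raises(ValueError):
            calibrate_diagnosis_probability(0.25, 0.25, "geometric")

    def test_nonpositive_ttd_rejected(self):
        with pytest.raises(ValueError):
            calibrate_diagnosis_probability(0.0, 0.25)


class TestTransitionMatrix:
    def test_identity_when_nothing_happens(self):
        np.testing.assert_array_equal(transition_matrix(0.0, 0.0), np.eye(3))

    def test_all_survivors_diagnosed(self):
        m = transition_matrix(1.0, 0.0)
        np.testing.assert_array_equal(m[MarkovState.UNDIAGNOSED], [0.0, 1.0, 0.0])

    def test_death_takes_precedence(self):
        m = transition_matrix(0.029, 0.0004)
        row = m[MarkovState.UNDIAGNOSED]
        assert row[0] == pytest.approx(0.9706116, abs=1e-9)
        assert row[1] == pytest.approx(0.0289884, abs=1e-9)
        assert row[2] == 0.0004
        assert abs(row.sum() - 1.0) < 1e-15

    def test_rows_stochastic(self):
        m = transition_matrix(0.37, 0.12)
        np.testing.assert_allclose(m.sum(axis=1), 1.0, atol=1e-15)
        assert np.all(m >= 0)

    def test_dead_absorbing_and_no_undiagnosis(self):
        m = transition_matrix(0.5, 0.1)
        np.testing.assert_array_equal(m[MarkovState.DEAD], [0, 0, 1])
        assert m[MarkovState.DIAGNOSED, MarkovState.UNDIAGNOSED] == 0.0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            transition_matrix(1.2, 0.0)


class TestRunCohort:
    def test_mass_conserved_every_cycle(self, trace_male):
        np.testing.assert_allclose(trace_male.occupancy.sum(axis=1), 1.0, atol=1e-10)

    def test_monotone_occupancies(self, trace_male):
        occ = trace_male.occupancy
        assert np.all(np.diff(occ[:, MarkovState.DEAD]) >= -1e-12)
        assert np.all(np.diff(occ[:, MarkovState.UNDIAGNOSED]) <= 1e-12)
        # cumulative diagnosed + dead mass never shrinks
        assert np.all(np.diff(occ[:, 1] + occ[:, 2]) >= -1e-12)

    def test_terminal_cycle_fully_dead(self, trace_male):
        np.testing.assert_allclose(trace_male.occupancy[-1], [0, 0, 1], atol=1e-8)

    def test_no_mortality_trace_recovers_target_delay(self, params, no_mortality_table):
        """With death switched off, the diagnosis-time distribution must mean
        back to the calibrated 8.5 years within one half-cycle."""
        trace = run_cohort(params, no_mortality_table, "male")
        assert mean_time_to_diagnosis(trace) == pytest.approx(8.5, abs=0.125)

    def test_zero_diagnosis_reduces_to_survival_curve(self, params, life_table):
        p0 = params.updated({"mean_time_to_diagnosis": 1e9})
        trace = run_cohort(p0, life_table, "female")
        # undiagnosed occupancy is (numerically) the SMR-adjusted survival curve
        from axspa_burden import cycle_death_probability

        surv = 1.0
        expected = [1.0]
        for t in range(trace.n_cycles - 1):
            age = p0.onset_age + t * 0.25
            surv *= 1 - cycle_death_probability(life_table, age, "female", p0.smr_female, 0.25)
            expected.append(surv)
        np.testing.assert_allclose(
            trace.occupancy[:, MarkovState.UNDIAGNOSED], expected, atol=1e-6
        )

    def test_newly_diagnosed_accounts_for_diagnosed_inflow(self, trace_female):
        occ_d = trace_female.occupancy[:, MarkovState.DIAGNOSED]
        nd = trace_female.newly_diagnosed
        # diagnosed stock grows by inflow minus deaths, so inflow bounds growth
        assert np.all(np.diff(occ_d) <= nd[1:] + 1e-12)
        assert nd.sum() + trace_female.occupancy[-1, MarkovState.UNDIAGNOSED] <= 1.0 + 1e-9


class TestMixCohorts:
    def test_pct_male_one_is_identity(self, trace_male, trace_female):
        mixed = mix_cohorts(trace_male, trace_female, 1.0)
        np.testing.assert_array_equal(mixed.occupancy, trace_male.occupancy)

    def test_identical_traces_fixed_point(self, trace_male):
        mixed = mix_cohorts(trace_male, trace_male, 0.5)
        np.testing.assert_allclose(mixed.occupancy, trace_male.occupancy, atol=1e-15)

    def test_mixing_is_linear(self, trace_male, trace_female):
        mixed = mix_cohorts(trace_male, trace_female, 0.64)
        expected = 0.64 * trace_male.occupancy + 0.36 * trace_female.occupancy
        np.testing.assert_allclose(mixed.occupancy, expected, atol=1e-9)

    def test_mismatched_grids_rejected(self, trace_male):
        short = CohortTrace(
            cycle_index=trace_male.cycle_index[:-1],
            attained_age=trace_male.attained_age[:-1],
            occupancy=trace_male.occupancy[:-1],
            newly_diagnosed=trace_male.newly_diagnosed[:-1],
        )
        with pytest.raises(ValueError, match="grid"):
            mix_cohorts(trace_male, short, 0.64)


def test_cohort_pair_always_mixable():
    """Life tables where the alive-mass cutoff fires early for one sex must
    still yield a common cycle grid for mixing."""
    from axspa_burden import (
        SyntheticScenario,
        generate_life_table,
        generate_parameter_set,
        run_cohort_pair,
    )

    for seed in range(6):
        p = generate_parameter_set(SyntheticScenario(seed=seed))
        lt = generate_life_table(seed)
        traces = run_cohort_pair(p, lt)
        assert traces["male"].n_cycles == traces["female"].n_cycles
        mix_cohorts(traces["male"], traces["female"], p.pct_male).validate()


def test_microsimulation_agrees_with_cohort(params, life_table):
    """Individual-level oracle: 50 000 simulated patients drawing per-cycle
    death/diagnosis events reproduce the cohort occupancies within Monte-
    Carlo error (a larger replication runs in the acceptance suite)."""
    from axspa_burden import calibrate_diagnosis_probability, cycle_death_probability

    n = 50_000
    rng = np.random.default_rng(2026)
    trace = run_cohort(params, life_table, "male")
    p_diag = calibrate_diagnosis_probability(params.mean_time_to_diagnosis, 0.25)
    state = np.zeros(n, dtype=np.int8)
    for t in range(trace.n_cycles - 1):
        age = params.onset_age + t * 0.25
        p_death = cycle_death_probability(life_table, age, "male", params.smr_male, 0.25)
        alive = state < 2
        dies = alive & (rng.random(n) < p_death)
        state[dies] = 2
        undiag = (state == 0) & ~dies
        state[undiag & (rng.random(n) < p_diag)] = 1
        if t % 40 == 0 or t == trace.n_cycles - 2:
            occ = trace.occupancy[t + 1]
            for s in range(3):
                frac = np.mean(state == s)
                se = math.sqrt(max(occ[s] * (1 - occ[s]), 1e-12) / n)
                # 4-SE band only where the Gaussian SE is meaningful
                if n * min(occ[s], 1 - occ[s]) >= 25:
                    assert abs(frac - occ[s]) < 4 * se + 1e-6
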