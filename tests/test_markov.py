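"""Cohort engine: conversions, transition matrices, cohort propagation."""

import dataclasses

import numpy as np
import pytest

import renalcea as rc
from renalcea.lifetable import LifeTable
from renalcea.markov import REFERENCE_CASE, HealthState, state_reward
from renalcea.synthetic import random_parameter_set, toy_closed_form


def _flat_life_table(q_annual, min_age=0, max_age=120):
    qx = tuple([q_annual] * (max_age - min_age) + [1.0])
    return LifeTable(tuple(range(min_age, max_age + 1)), qx)


def _no_disease(ps):
    return dataclasses.replace(
        ps,
        p_non_r0=0.0,
        p_local_recurrence=0.0,
        p_metastases_no_tumor=0.0,
        p_metastases_localized=0.0,
        p_successful_recurrence_surgery=0.0,
        excess_death_metastatic=0.0,
        excess_death_localized=0.0,
    )


class TestConversions:
    @pytest.mark.parametrize("p", [0.0, 1.0])
    def test_annual_to_monthly_endpoints(self, p):
        assert rc.annual_to_monthly_prob(p) == p

    def test_annual_to_monthly_composes(self):
        m = rc.annual_to_monthly_prob(0.13)
        assert m == pytest.approx(0.011538, abs=1e-6)
        assert 1 - (1 - m) ** 12 == pytest.approx(0.13, abs=1e-12)

    def test_annual_to_monthly_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            rc.annual_to_monthly_prob(1.5)

    @pytest.mark.parametrize(
        "p1,p2,expected", [(0.0, 0.3, 0.3), (1.0, 0.3, 1.0), (0.01, 0.02, 0.0298)]
    )
    def test_combine_competing_risks(self, p1, p2, expected):
        assert rc.combine_competing_risks(p1, p2) == pytest.approx(expected, abs=1e-12)

    def test_discount_factor(self):
        assert rc.discount_factor(0, 0.03) == 1.0
        assert rc.discount_factor(12, 0.03) == pytest.approx(1 / 1.03, abs=1e-9)
        assert rc.discount_factor(240, 0.0) == 1.0


class TestTransitionMatrix:
    def test_identity_when_nothing_happens(self, baseline):
        ps = _no_disease(baseline)
        lt = _flat_life_table(0.0)
        m = rc.build_transition_matrix(ps, lt, 62 * 12)
        assert np.allclose(m, np.eye(4), atol=1e-15)

    def test_dead_row_is_absorbing(self, baseline, life_table):
        m = rc.build_transition_matrix(baseline, life_table, 62 * 12)
        assert np.array_equal(m[HealthState.DEAD], [0, 0, 0, 1])

    def test_baseline_rows_stochastic_and_death_ordering(self, baseline, life_table):
        m = rc.build_transition_matrix(baseline, life_table, 62 * 12)
        assert np.allclose(m.sum(axis=1), 1.0, atol=1e-12)
        assert np.all(m >= 0) and np.all(m <= 1)
        # 35% metastatic excess death dwarfs the 3.5% localized one
        assert m[HealthState.METASTATIC, HealthState.DEAD] > m[HealthState.LOCALIZED, HealthState.DEAD]

    def test_rows_stochastic_at_every_age_for_random_sets(self, life_table):
        rng = np.random.default_rng(42)
        for _ in range(5):
            ps = random_parameter_set(rng)
            for age in (62, 75, 99, 100):
                m = rc.build_transition_matrix(ps, life_table, age * 12)
                assert np.allclose(m.sum(axis=1), 1.0, atol=1e-12)
                assert np.all(m >= -1e-15)


class TestStateRewards:
    def test_dead_accrues_nothing(self, baseline):
        assert state_reward(HealthState.DEAD, 7, "timely", baseline) == (0.0, 0.0)

    def test_first_year_metastatic(self, baseline):
        cost, qaly = state_reward(HealthState.METASTATIC, 5, "delayed", baseline)
        assert cost == 2086.42
        assert qaly == pytest.approx(0.055, abs=1e-12)  # 0.66/12

    def test_later_year_localized(self, baseline):
        cost, qaly = state_reward(HealthState.LOCALIZED, 14, "timely", baseline)
        assert cost == 212.67
        assert qaly == pytest.approx(0.0625, abs=1e-12)  # 0.75/12

    def test_reference_case_windows_costs_but_not_qalys(self, baseline):
        cost, qaly = state_reward(HealthState.LOCALIZED, 20, "timely", baseline, REFERENCE_CASE)
        assert cost == 0.0 and qaly == pytest.approx(0.0625)
        cost, _ = state_reward(HealthState.LOCALIZED, 3, "timely", baseline, REFERENCE_CASE)
        assert cost == baseline.monthly_cost_no_tumor


class TestRunCohort:
    def test_entry_dead_yields_zero_totals(self, baseline, life_table):
        tr = rc.run_cohort([0, 0, 0, 1], baseline, life_table, horizon_months=24)
        assert tr.total_cost == 0.0 and tr.total_qalys == 0.0

    def test_occupancy_conserved_each_cycle_random_sets(self, life_table):
        rng = np.random.default_rng(7)
        for _ in range(5):
            ps = random_parameter_set(rng)
            tr = rc.run_cohort([0, 1, 0, 0], ps, life_table)
            assert np.allclose(tr.occupancy.sum(axis=1), 1.0, atol=1e-10)
            assert np.all(tr.occupancy >= -1e-12)

    def test_dead_occupancy_nondecreasing(self, baseline, life_table):
        tr = rc.run_cohort([0.5, 0.3, 0.2, 0.0], baseline, life_table)
        dead = tr.occupancy[:, HealthState.DEAD]
        assert np.all(np.diff(dead) >= -1e-12)

    def test_totals_decrease_with_discount_rate(self, baseline, life_table):
        lo = dataclasses.replace(baseline, annual_discount=0.01)
        hi = dataclasses.replace(baseline, annual_discount=0.05)
        tr_lo = rc.run_cohort([1, 0, 0, 0], lo, life_table)
        tr_hi = rc.run_cohort([1, 0, 0, 0], hi, life_table)
        assert tr_hi.total_cost <= tr_lo.total_cost
        assert tr_hi.total_qalys <= tr_lo.total_qalys

    def test_totals_equal_cycle_sums(self, baseline, life_table):
        tr = rc.run_cohort([1, 0, 0, 0], baseline, life_table)
        assert tr.total_cost == pytest.approx(tr.cycle_cost.sum(), rel=1e-12)
        assert tr.total_qalys == pytest.approx(tr.cycle_qaly.sum(), rel=1e-12)

    def test_two_state_closed_form_equivalence(self, baseline):
        """A constant-hazard alive/dead chain matches the geometric series
        to 1e-9 (engine-vs-formula oracle)."""
        q_m = 0.03
        q_a = 1 - (1 - q_m) ** 12
        lt = _flat_life_table(q_a, min_age=0, max_age=80)
        ps = dataclasses.replace(
            _no_disease(baseline),
            start_age_years=0,
            annual_discount=0.03,
            monthly_cost_no_tumor=100.0,
            utility_no_tumor=0.8,
        )
        tr = rc.run_cohort([1, 0, 0, 0], ps, lt, horizon_months=600)
        cost, qalys = toy_closed_form(q_m, 0.8, 100.0, 0.03, horizon=tr.n_cycles)
        assert tr.total_cost == pytest.approx(cost, abs=1e-9)
        assert tr.total_qalys == pytest.approx(qalys, abs=1e-9)

    def test_invalid_entry_distribution_rejected(self, baseline, life_table):
        with pytest.raises(ValueError):
            rc.run_cohort([0.5, 0.5, 0.5, 0.0], baseline, life_table, horizon_months=12)
        with pytest.raises(ValueError):
            rc.run_cohort([1, 0, 0, 0], baseline, life_table, horizon_months=0)

    def test_trace_export_schema(self, baseline, life_table):
        df = rc.run_cohort([1, 0, 0, 0], baseline, life_table, horizon_months=6).to_frame()
        assert list(df.columns) == [
            "cycle", "no_tumor", "localized", "metastatic", "dead",
            "discounted_cost", "discounted_qaly",
        ]
        assert len(df) == 6
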