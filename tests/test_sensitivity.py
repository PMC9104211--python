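"""Tornado DSA, PSA sampling, and acceptability curves."""

import dataclasses

import numpy as np
import pytest

import renalcea as rc
from renalcea.parameters import DistributionSpec, get_parameter, set_parameter
from renalcea.sensitivity import (
    ModelContext,
    _batched_pathway_totals,
    _draw_parameter_matrix,
    default_dsa_ranges,
    sample_parameter,
)


@pytest.fixture(scope="module")
def ctx(life_table):
    return ModelContext(life_table=life_table, topology=rc.REFERENCE_CASE)


class TestOneWayDsa:
    def test_collapsed_range_has_zero_span(self, baseline, ctx):
        base = get_parameter(baseline, "exam_cost_ceus")
        e = rc.one_way_dsa(baseline, "exam_cost_ceus", base, base, ctx)
        assert e.span == 0.0

    def test_inert_parameter_has_zero_span(self, baseline, ctx):
        e = rc.one_way_dsa(baseline, "cost_no_action", 0.0, 0.0, ctx)
        assert e.span == 0.0

    def test_ceus_exam_cost_sweep_keeps_ceus_optimal(self, baseline, ctx):
        """±20% on the CEUS tariff does not overturn its preference at the
        100k USD/QALY willingness-to-pay."""
        base = get_parameter(baseline, "exam_cost_ceus")
        e = rc.one_way_dsa(baseline, "exam_cost_ceus", 0.8 * base, 1.2 * base, ctx)
        assert e.outcome_at_low > 0 and e.outcome_at_high > 0

    def test_domain_violations_rejected(self, baseline, ctx):
        with pytest.raises(ValueError):
            rc.one_way_dsa(baseline, "sensitivity_ceus", 0.5, 1.2, ctx)
        with pytest.raises(ValueError):
            rc.one_way_dsa(baseline, "exam_cost_ct", 100.0, 50.0, ctx)  # low > high


class TestTornado:
    def test_sorted_by_descending_span(self, baseline, ctx):
        entries = rc.tornado(baseline, model_context=ctx)
        spans = [e.span for e in entries]
        assert spans == sorted(spans, reverse=True)
        swept = {e.parameter for e in entries}
        assert {"sensitivity_ceus", "specificity_mri", "exam_cost_ct", "cost_delayed_treatment"} <= swept

    def test_empty_range_set(self, baseline, ctx):
        assert rc.tornado(baseline, {}, ctx) == []

    def test_duplicate_parameter_rejected(self, baseline, ctx):
        with pytest.raises(ValueError, match="duplicated"):
            rc.tornado(baseline, [("wtp", 1.0, 2.0), ("wtp", 1.0, 2.0)], ctx)

    def test_collapsed_ranges_recover_base_case(self, baseline, ctx):
        collapsed = {
            pid: (get_parameter(baseline, pid), get_parameter(baseline, pid))
            for pid in default_dsa_ranges(baseline)
        }
        entries = rc.tornado(baseline, collapsed, ctx)
        base_outcome = ctx.outcome(baseline)
        assert all(e.span == 0.0 for e in entries)
        assert all(e.outcome_at_low == base_outcome for e in entries)

    def test_default_probability_ranges_clipped_to_unit_interval(self, baseline):
        ranges = default_dsa_ranges(baseline)
        lo, hi = ranges["sensitivity_ceus"]
        assert hi == 1.0  # 0.991 * 1.2 clipped
        assert lo == pytest.approx(0.991 * 0.8)


class TestSampleParameter:
    def test_fixed_always_returns_mean(self):
        rng = np.random.default_rng(0)
        spec = DistributionSpec("fixed", 233.0)
        assert sample_parameter(spec, rng) == 233.0

    def test_beta_moment_recovery(self):
        rng = np.random.default_rng(1)
        draws = sample_parameter(DistributionSpec("beta", 0.75, 0.2), rng, size=30_000)
        se = draws.std(ddof=1) / np.sqrt(draws.size)
        assert abs(draws.mean() - 0.75) < 3 * se

    def test_gamma_moment_recovery(self):
        rng = np.random.default_rng(2)
        draws = sample_parameter(DistributionSpec("gamma", 4231.0, 0.2), rng, size=30_000)
        se_mean = draws.std(ddof=1) / np.sqrt(draws.size)
        assert abs(draws.mean() - 4231.0) < 3 * se_mean
        cv_hat = draws.std(ddof=1) / draws.mean()
        # SE of the sample cv is ~ cv/sqrt(2n) for near-normal shapes
        assert abs(cv_hat - 0.2) < 3 * 0.2 / np.sqrt(2 * draws.size)

    def test_infeasible_beta_moments_error_names_parameter(self):
        rng = np.random.default_rng(3)
        with pytest.raises(ValueError, match="sensitivity_ceus"):
            sample_parameter(DistributionSpec("beta", 0.991, 0.2), rng, name="sensitivity_ceus")


class TestRunPsa:
    def test_same_seed_is_bit_identical(self, baseline, life_table):
        a = rc.run_psa(baseline, life_table, 200, seed=17)
        b = rc.run_psa(baseline, life_table, 200, seed=17)
        assert np.array_equal(a.costs, b.costs)
        assert np.array_equal(a.effects, b.effects)
        c = rc.run_psa(baseline, life_table, 200, seed=18)
        assert not np.array_equal(a.costs, c.costs)

    def test_all_fixed_specs_reproduce_base_case(self, baseline, life_table):
        fixed = {pid: DistributionSpec("fixed", d.mean) for pid, d in baseline.psa_dist.items()}
        ps = dataclasses.replace(baseline, psa_dist=fixed)
        psa = rc.run_psa(ps, life_table, 4, seed=5)
        base = rc.evaluate_all_strategies(ps, life_table)
        for k, r in enumerate(base):
            assert np.allclose(psa.costs[:, k], r.expected_cost, rtol=1e-9)
            assert np.allclose(psa.effects[:, k], r.expected_effect, rtol=1e-9)

    def test_batched_engine_matches_scalar_on_sampled_draws(self, baseline, life_table):
        """The vectorized PSA path reproduces the scalar cohort engine for
        the same sampled parameter values."""
        n = 3
        draws = _draw_parameter_matrix(baseline, n, seed=99)
        horizon = (life_table.max_age - baseline.start_age_years) * 12
        costs, qalys = _batched_pathway_totals(draws, baseline, life_table, n, horizon, rc.STANDARD)
        for i in range(n):
            ps_i = baseline
            for pid, col in draws.items():
                ps_i = set_parameter(ps_i, pid, float(col[i]))
            for s, state in enumerate((rc.HealthState.NO_TUMOR, rc.HealthState.LOCALIZED, rc.HealthState.METASTATIC)):
                entry = [0.0] * 4
                entry[state] = 1.0
                tr = rc.run_cohort(entry, ps_i, life_table, horizon_months=horizon)
                assert costs[i, s] == pytest.approx(tr.total_cost, rel=1e-8)
                assert qalys[i, s] == pytest.approx(tr.total_qalys, rel=1e-8)


class TestCeac:
    def test_single_iteration_winner_takes_all(self, baseline, life_table):
        psa = rc.run_psa(baseline, life_table, 1, seed=0)
        curve = rc.ceac(psa, [100_000.0])
        row = curve.loc[100_000.0]
        assert sorted(row) == [0.0, 0.0, 1.0]

    def test_zero_wtp_acceptance_is_fraction_cheapest(self, baseline, life_table):
        psa = rc.run_psa(baseline, life_table, 100, seed=8)
        row = rc.ceac(psa, [0.0]).loc[0.0]
        cheapest = np.bincount(psa.costs.argmin(axis=1), minlength=len(psa.strategies)) / 100
        for k, s in enumerate(psa.strategies):
            assert row[s] == pytest.approx(cheapest[k], abs=1e-12)

    def test_curves_normalized_across_grid(self, baseline, life_table):
        psa = rc.run_psa(baseline, life_table, 300, seed=4)
        curves = rc.ceac(psa)
        sums = curves.sum(axis=1).to_numpy()
        assert np.allclose(sums, 1.0, atol=1e-12)
        assert (curves.to_numpy() >= 0).all() and (curves.to_numpy() <= 1).all()

    def test_empty_grid_rejected(self, baseline, life_table):
        psa = rc.run_psa(baseline, life_table, 2, seed=0)
        with pytest.raises(ValueError):
            rc.ceac(psa, [])
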