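import dataclasses

import numpy as np
import pytest

from gcsf_cea.cea import build_frontier, evaluate_strategies, nmb
from gcsf_cea.parameters import base_strategies, strategy_by_id
from gcsf_cea.sensitivity import (
    DistributionFitError,
    DistributionSpec,
    NoCrossingError,
    build_distributions,
    one_way,
    run_psa,
    run_scenario,
    run_tornado,
    sample_psa,
    solve_threshold,
    threshold_search,
)

PP_LENO_VS_NONE = ("pp_lenograstim", "none")
PP_PEG_VS_PP_LENO = ("pp_pegfilgrastim", "pp_lenograstim")


def _pair(ids):
    return tuple(strategy_by_id(s) for s in ids)


class TestDistributions:
    @pytest.mark.parametrize(
        "name", ["p_fn_cycle1", "cost_fn_event", "rr_history", "u_fn_decrement", "los_fn"]
    )
    def test_draw_mean_calibrated_to_base(self, params, name):
        spec = build_distributions(params)[name]
        rng = np.random.default_rng(5)
        draws = spec.sample(rng, size=100_000)
        assert np.mean(draws) == pytest.approx(params.value_of(name), rel=0.02)

    def test_fixed_price_never_varies(self, params):
        spec = build_distributions(params)["price_pegfilgrastim"]
        rng = np.random.default_rng(0)
        assert np.all(spec.sample(rng, size=1000) == 16_626)

    def test_lognormal_quantiles_recover_the_stated_range(self, params):
        # rr_history fitted from base 2.4 and 95% range (2.2, 2.6)
        spec = build_distributions(params)["rr_history"]
        rng = np.random.default_rng(11)
        draws = spec.sample(rng, size=200_000)
        lo, hi = np.percentile(draws, [2.5, 97.5])
        assert lo == pytest.approx(2.2, abs=0.03)
        assert hi == pytest.approx(2.6, abs=0.03)

    def test_beta_support_and_infeasible_moments(self, params):
        spec = build_distributions(params)["p_fn_cycle1"]
        rng = np.random.default_rng(2)
        draws = spec.sample(rng, size=10_000)
        assert np.all((draws >= 0) & (draws <= 1))
        with pytest.raises(DistributionFitError, match="nearly_degenerate"):
            DistributionSpec.fit("nearly_degenerate", "beta", 0.001, 0.0, 0.9)


class TestSamplePsa:
    def test_deterministic_given_seed(self, params):
        d1 = sample_psa(params, np.random.default_rng(9))
        d2 = sample_psa(params, np.random.default_rng(9))
        assert d1 == d2

    def test_prices_fixed_and_risks_redrawn(self, params):
        draw = sample_psa(params, np.random.default_rng(1))
        assert draw.drugs["pegfilgrastim"].price == 16_626
        assert draw.p_fn_cycle1 != params.p_fn_cycle1
        # biosimilar effectiveness follows the redrawn reference drug
        assert draw.drug_rr_tiers("pegfilgrastim_biosimilar") == draw.drug_rr_tiers(
            "pegfilgrastim"
        )


class TestPsa:
    def test_probabilities_sum_to_one(self, params, life_table):
        ceac = run_psa(base_strategies(), params, life_table, n_iter=50, seed=4)
        assert np.allclose(ceac.probabilities.sum(axis=1), 1.0)
        assert np.all((ceac.probabilities >= 0) & (ceac.probabilities <= 1))

    def test_all_fixed_distributions_reproduce_base_case_every_iteration(
        self, params, life_table
    ):
        frozen = dataclasses.replace(
            params, dist_family={k: "fixed" for k in params.dist_family}
        )
        ceac = run_psa(base_strategies(), frozen, life_table, n_iter=20, seed=8)
        results = evaluate_strategies(base_strategies(), params, life_table)
        for i, w in enumerate(ceac.wtp):
            best = max(results, key=lambda r: nmb(r, w)).strategy.label
            assert ceac.probabilities[i, ceac.strategies.index(best)] == 1.0

    def test_same_seed_identical_runs(self, params, life_table):
        a = run_psa(base_strategies(), params, life_table, n_iter=30, seed=12)
        b = run_psa(base_strategies(), params, life_table, n_iter=30, seed=12)
        assert np.array_equal(a.probabilities, b.probabilities)

    def test_single_iteration_gives_indicator_curves(self, params, life_table):
        ceac = run_psa(base_strategies(), params, life_table, n_iter=1, seed=3)
        assert set(np.unique(ceac.probabilities)) <= {0.0, 1.0}


class TestScenarios:
    def test_scenario1_with_null_hr_equals_base_case(self, params, life_table):
        p1 = params.with_value("hr_rdi_low", 1.0)
        base = build_frontier(evaluate_strategies(base_strategies(), p1, life_table))
        sc1 = run_scenario(1, p1, life_table)
        for e_base, e_sc in zip(base.entries, sc1.entries):
            assert e_base.result.strategy.label == e_sc.result.strategy.label
            assert e_base.result.total_qalys == pytest.approx(e_sc.result.total_qalys, abs=1e-12)
            assert e_base.status == e_sc.status

    def test_scenario2_biosimilar_dominates_reference(self, params, life_table):
        fr = run_scenario(2, params, life_table)
        df = fr.to_dataframe().set_index("strategy")
        assert len(df) == 11
        assert df.loc["PP with pegfilgrastim biosimilar", "cost"] == pytest.approx(
            90_039, abs=60
        )
        assert df.loc["PP with pegfilgrastim", "status"] == "dominated"
        # equal QALYs, lower price: strong dominance of the reference product
        assert df.loc["PP with pegfilgrastim", "qalys"] == pytest.approx(
            df.loc["PP with pegfilgrastim biosimilar", "qalys"], abs=1e-12
        )


class TestOneWay:
    def test_zero_width_range_gives_zero_span(self, params, life_table):
        base = params.value_of("p_fn_death")
        frozen = dataclasses.replace(
            params, ranges={**params.ranges, "p_fn_death": (base, base)}
        )
        entry = one_way("p_fn_death", _pair(PP_LENO_VS_NONE), frozen, life_table)
        assert entry.span == 0.0

    def test_unknown_parameter_rejected(self, params, life_table):
        with pytest.raises(Exception, match="no_such"):
            one_way("no_such", _pair(PP_LENO_VS_NONE), params, life_table)

    def test_peg_rr_is_widest_lever_for_peg_vs_leno(self, params, life_table):
        entries = run_tornado(_pair(PP_PEG_VS_PP_LENO), params, life_table)
        assert entries[0].parameter == "rr_pegfilgrastim"

    def test_influential_parameters_for_leno_vs_none(self, params, life_table):
        """Lenograstim effectiveness, baseline FN risk and the discount rate
        top the tornado for primary lenograstim prophylaxis vs none."""
        entries = run_tornado(_pair(PP_LENO_VS_NONE), params, life_table)
        top4 = {e.parameter for e in entries[:4]}
        assert "discount_rate" in top4
        assert "p_fn_cycle1" in top4
        assert top4 & {"rr_lenograstim_c12", "rr_lenograstim_c3plus"}
        top6 = {e.parameter for e in entries[:6]}
        assert "p_fn_death" in top6

    def test_entries_sorted_by_descending_span(self, params, life_table):
        entries = run_tornado(_pair(PP_LENO_VS_NONE), params, life_table)
        spans = [e.span for e in entries]
        assert spans == sorted(spans, reverse=True)


class TestThreshold:
    def test_analytic_linear_model_recovered_exactly(self):
        # ICER(x) = 4e6 * x + 1e5 crosses 1e6 at x = 0.225
        root = solve_threshold(lambda x: 4e6 * x + 1e5, 1e6, (0.0, 1.0), tol=1e-6)
        assert root == pytest.approx(0.225, abs=1e-6)

    def test_target_at_base_returns_base_value(self, params, life_table):
        from gcsf_cea.sensitivity import _pairwise_icer

        a, b = _pair(PP_PEG_VS_PP_LENO)
        base_icer = _pairwise_icer(a, b, params, life_table)
        root = threshold_search(
            "rr_pegfilgrastim", (a, b), base_icer, params, life_table, bracket=(0.3, 0.4)
        )
        assert root == pytest.approx(0.334, abs=1e-6)

    def test_no_crossing_raises(self, params, life_table):
        with pytest.raises(NoCrossingError):
            solve_threshold(lambda x: x, 10.0, (0.0, 1.0))
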