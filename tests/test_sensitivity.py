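"""Deterministic and probabilistic sensitivity analyses."""

import numpy as np
import pytest

import osteocea as oc
from osteocea.sensitivity import (
    DSASpec,
    PSASpec,
    SensitivityError,
    ceac,
    one_way_dsa,
    packaged_scenarios,
    pairwise_icer,
    psa,
    scenario,
)

PAIR = ("denosumab", "generic_alendronate")


class TestOneWayDsa:
    def test_zero_width_spec_reproduces_base_icer(self, two_strategy_cfg):
        base = pairwise_icer(oc.run_all(two_strategy_cfg), *PAIR)[0]
        spec = DSASpec("strategies.denosumab.rr_hip", 0.38, 0.38)
        table = one_way_dsa(two_strategy_cfg, [spec], PAIR)
        assert table.loc[0, "icer_low"] == pytest.approx(base, rel=1e-12)
        assert table.loc[0, "icer_high"] == pytest.approx(base, rel=1e-12)
        assert table.loc[0, "width"] == pytest.approx(0.0, abs=1e-9)

    def test_dearer_denosumab_raises_its_icer(self, two_strategy_cfg):
        base_cost = two_strategy_cfg.strategy("denosumab").annual_drug_cost
        base = pairwise_icer(oc.run_all(two_strategy_cfg), *PAIR)[0]
        spec = DSASpec.pct("strategies.denosumab.annual_drug_cost", base_cost)
        table = one_way_dsa(two_strategy_cfg, [spec], PAIR)
        assert table.loc[0, "icer_low"] < base < table.loc[0, "icer_high"]

    def test_hip_efficacy_bound_lowers_icer(self, two_strategy_cfg):
        spec = DSASpec("strategies.denosumab.rr_hip", 0.18, 0.78)
        table = one_way_dsa(two_strategy_cfg, [spec], PAIR)
        assert table.loc[0, "icer_low"] < table.loc[0, "icer_high"]

    def test_rows_sorted_by_width_and_label_invariant(self, two_strategy_cfg):
        specs = [
            DSASpec("strategies.denosumab.annual_drug_cost", 1237.5, 2062.5, label="x"),
            DSASpec("strategies.denosumab.rr_hip", 0.38, 0.38, label="y"),
        ]
        table = one_way_dsa(two_strategy_cfg, specs, PAIR)
        assert list(table["width"]) == sorted(table["width"], reverse=True)
        relabelled = [
            DSASpec("strategies.denosumab.annual_drug_cost", 1237.5, 2062.5, label="b"),
            DSASpec("strategies.denosumab.rr_hip", 0.38, 0.38, label="a"),
        ]
        table2 = one_way_dsa(two_strategy_cfg, relabelled, PAIR)
        assert list(table2["path"]) == list(table["path"])

    def test_unknown_path_errors(self, two_strategy_cfg):
        with pytest.raises(oc.ConfigError, match="unknown parameter"):
            one_way_dsa(two_strategy_cfg, [DSASpec("no.such.param", 0, 1)], PAIR)

    def test_inverted_bounds_rejected(self):
        with pytest.raises(SensitivityError, match="low"):
            DSASpec("strategies.denosumab.rr_hip", 0.78, 0.18)


class TestScenarios:
    def test_empty_overrides_identical_to_base(self, two_strategy_cfg):
        base = oc.run_cea(two_strategy_cfg).to_frame()
        assert scenario(two_strategy_cfg, {}).to_frame().equals(base)

    def test_generic_price_cut_is_linear_in_drug_component(self, base_cfg):
        zol = base_cfg.strategy("zoledronate")
        base = oc.run_strategy(base_cfg, zol)
        overrides = packaged_scenarios(base_cfg)["generic_zoledronate"]
        cheap_cfg = oc.with_parameters(base_cfg, overrides)
        cut = oc.run_strategy(cheap_cfg, cheap_cfg.strategy("zoledronate"))
        expected_saving = 0.35 * base.components["drug"]
        assert base.cost - cut.cost == pytest.approx(expected_saving, rel=1e-9)
        assert cut.qalys == pytest.approx(base.qalys, rel=1e-12)

    def test_packaged_offset_scenario_sets_comparator_offsets(self, base_cfg):
        overrides = packaged_scenarios(base_cfg)["long_offset"]
        cfg = oc.with_parameters(base_cfg, overrides)
        assert cfg.strategy("denosumab").offset_years == 2.0
        assert cfg.strategy("teriparatide").offset_years == 2.5
        assert cfg.strategy("generic_alendronate").offset_years == 5.0
        # longer offset cannot make a strategy less effective
        base_q = oc.run_strategy(base_cfg, base_cfg.strategy("generic_alendronate")).qalys
        long_q = oc.run_strategy(cfg, cfg.strategy("generic_alendronate")).qalys
        assert long_q >= base_q


class TestPsaSpecs:
    def test_negative_dispersion_rejected(self):
        with pytest.raises(SensitivityError, match="dispersion"):
            PSASpec("x", "lognormal", 1.0, se=-0.1)

    def test_overlarge_beta_dispersion_rejected(self):
        with pytest.raises(SensitivityError, match="beta"):
            PSASpec("x", "beta", 0.5, se=0.6)

    def test_degenerate_spec_is_point_mass(self):
        spec = PSASpec("x", "gamma", 100.0, se=0.0)
        draws = spec.sample(np.random.default_rng(0), 50)
        assert (draws == 100.0).all()

    @pytest.mark.parametrize(
        "family,mean,se", [("lognormal", 0.5, 0.1), ("gamma", 28112, 7028), ("beta", 0.2, 0.05)]
    )
    def test_moments_recovered(self, family, mean, se):
        spec = PSASpec("x", family, mean, se=se)
        draws = spec.sample(np.random.default_rng(1), 200_000)
        assert draws.mean() == pytest.approx(mean, rel=0.01)
        assert draws.std() == pytest.approx(se, rel=0.02)

    def test_lognormal_ci_quantiles_recovered(self):
        spec = PSASpec("x", "lognormal", 0.38, ci=(0.18, 0.78))
        draws = spec.sample(np.random.default_rng(2), 200_000)
        lo, hi = np.quantile(draws, [0.025, 0.975])
        assert lo == pytest.approx(0.18, rel=0.02)
        assert hi == pytest.approx(0.78, rel=0.02)


class TestPsa:
    def test_same_seed_identical_draws(self, two_strategy_cfg):
        specs = oc.default_psa_specs(two_strategy_cfg)[:4]
        a = psa(two_strategy_cfg, specs, n_draws=3, seed=7)
        b = psa(two_strategy_cfg, specs, n_draws=3, seed=7)
        assert a.draws.equals(b.draws)
        assert a.parameters.equals(b.parameters)

    def test_adding_a_spec_leaves_other_streams_unchanged(self, two_strategy_cfg):
        specs = oc.default_psa_specs(two_strategy_cfg)
        short = psa(two_strategy_cfg, specs[:3], n_draws=4, seed=11).parameters
        extended = psa(two_strategy_cfg, specs[:4], n_draws=4, seed=11).parameters
        for col in short.columns:
            assert (short[col] == extended[col]).all()

    def test_degenerate_distributions_reproduce_base_case(self, two_strategy_cfg):
        specs = [
            PSASpec(s.path, s.family, s.mean, se=0.0)
            for s in oc.default_psa_specs(two_strategy_cfg)
        ]
        result = psa(two_strategy_cfg, specs, n_draws=2, seed=5)
        base = {t.name: t for t in oc.run_all(two_strategy_cfg)}
        for row in result.draws.itertuples():
            assert row.cost == pytest.approx(base[row.strategy].cost, rel=1e-12)
            assert row.qalys == pytest.approx(base[row.strategy].qalys, rel=1e-12)


class TestCeac:
    def test_single_draw_indicator(self, two_strategy_cfg):
        result = psa(two_strategy_cfg, oc.default_psa_specs(two_strategy_cfg)[:2], 1, seed=3)
        curves = ceac(result.draws, [0, 100_000])
        assert set(curves["probability"]) <= {0.0, 1.0}

    def test_threshold_zero_prefers_cheapest(self, two_strategy_cfg):
        result = psa(two_strategy_cfg, oc.default_psa_specs(two_strategy_cfg)[:4], 8, seed=9)
        curves = ceac(result.draws, [0.0])
        draws = result.draws.pivot(index="draw", columns="strategy", values="cost")
        cheapest_share = (draws["generic_alendronate"] < draws["denosumab"]).mean()
        got = curves[curves["strategy"] == "generic_alendronate"]["probability"].iloc[0]
        assert got == pytest.approx(cheapest_share)

    def test_probabilities_partition_to_one(self, two_strategy_cfg):
        result = psa(two_strategy_cfg, oc.default_psa_specs(two_strategy_cfg)[:4], 10, seed=13)
        curves = ceac(result.draws, np.arange(0, 200_001, 25_000))
        assert ((curves["probability"] >= 0) & (curves["probability"] <= 1)).all()
        sums = curves.groupby("threshold")["probability"].sum()
        assert np.allclose(sums, 1.0, atol=1e-12)
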