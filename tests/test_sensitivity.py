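"""Deterministic/probabilistic sensitivity, subgroup and scenario analyses."""

import numpy as np
import pytest

from colcea.report import run_base_case
from colcea.sensitivity import (
    DistFamily,
    DistributionSpec,
    PSAConfig,
    SensitivityError,
    TornadoSpec,
    bisect_crossing,
    default_psa_distributions,
    default_tornado_specs,
    one_way_dsa,
    pair_icer,
    pert_mean,
    run_psa,
    sample_parameter,
    scenario_xeliri,
    subgroup_model,
    threshold_multiplier,
    tornado,
)
from colcea.synthetic import SUBGROUP_MULTIPLIERS


@pytest.fixture(scope="module")
def t4_config(stage2_config):
    """Stage II T4 subgroup: both CAPOX arms sit on the frontier, so the
    pairwise ICER comparison of 6 vs 3 months is well-posed."""
    return subgroup_model(stage2_config, "t4",
                          SUBGROUP_MULTIPLIERS["high_risk_stage_ii"]["t4"])


COMPARISON = ("capox_6mo", "capox_3mo")


class TestSampleParameter:
    def test_fixed_returns_base(self, rng):
        spec = DistributionSpec("x", DistFamily.FIXED, 0.42)
        assert all(sample_parameter(spec, rng) == 0.42 for _ in range(5))

    def test_zero_sd_beta_degenerates_to_base(self, rng):
        spec = DistributionSpec("x", DistFamily.BETA, 0.3, 0.0)
        assert sample_parameter(spec, rng) == 0.3

    def test_beta_moments_match_method_of_moments_target(self, rng):
        spec = DistributionSpec("x", DistFamily.BETA, 0.3, 0.10)
        draws = np.array([sample_parameter(spec, rng) for _ in range(100_000)])
        assert draws.mean() == pytest.approx(0.3, abs=1e-3)
        assert draws.std() == pytest.approx(0.03, abs=2e-3)

    def test_gamma_moments(self, rng):
        spec = DistributionSpec("x", DistFamily.GAMMA, 9_748.0, 0.25)
        draws = np.array([sample_parameter(spec, rng) for _ in range(50_000)])
        assert draws.mean() == pytest.approx(9_748.0, rel=0.01)
        assert draws.std() == pytest.approx(0.25 * 9_748.0, rel=0.03)
        assert np.all(draws >= 0)

    def test_pert_bounded_with_classical_mean(self, rng):
        spec = DistributionSpec("x", DistFamily.PERT, 0.451,
                                minimum=0.307, maximum=0.600)
        draws = np.array([sample_parameter(spec, rng) for _ in range(50_000)])
        assert draws.min() >= 0.307 and draws.max() <= 0.600
        assert draws.mean() == pytest.approx(pert_mean(0.307, 0.451, 0.600), abs=2e-3)

    def test_infeasible_beta_sd_rejected_at_validation(self):
        with pytest.raises(SensitivityError, match="too large"):
            DistributionSpec("x", DistFamily.BETA, 0.99, 1.0)

    def test_beta_requires_unit_interval_base(self):
        with pytest.raises(SensitivityError):
            DistributionSpec("x", DistFamily.BETA, 1.5, 0.1)

    def test_pert_requires_ordered_min_mode_max(self):
        with pytest.raises(SensitivityError):
            DistributionSpec("x", DistFamily.PERT, 0.1, minimum=0.2, maximum=0.3)


class TestOneWayDsa:
    def test_multiplier_one_reproduces_base_icer(self, t4_config):
        base = pair_icer(t4_config, COMPARISON)
        lo, hi = one_way_dsa(t4_config,
                             TornadoSpec("strategies.capox_6mo.adjuvant_cost_zar",
                                         1.0, 2.0), COMPARISON)
        assert lo == pytest.approx(base, rel=1e-12)

    def test_raising_costlier_arms_cost_raises_its_icer(self, t4_config):
        lo, hi = one_way_dsa(t4_config,
                             TornadoSpec("strategies.capox_6mo.adjuvant_cost_zar",
                                         0.5, 2.0), COMPARISON)
        base = pair_icer(t4_config, COMPARISON)
        assert lo < base < hi

    def test_capox6_drug_cost_dominates_the_tornado(self, t4_config):
        df = tornado(t4_config, default_tornado_specs(t4_config, COMPARISON),
                     COMPARISON)
        assert df.iloc[0]["parameter"] == "strategies.capox_6mo.adjuvant_cost_zar"
        assert np.all(np.diff(df["spread"].to_numpy()) <= 1e-12)

    def test_discount_rate_sweep_brackets_base_icer(self, t4_config):
        base = pair_icer(t4_config, COMPARISON)
        lo, hi = one_way_dsa(t4_config,
                             TornadoSpec("settings.annual_discount_rate",
                                         0.0, 0.10, relative=False), COMPARISON)
        assert min(lo, hi) <= base <= max(lo, hi)

    def test_unresolvable_parameter_path_named_in_error(self, t4_config):
        from colcea.config import ConfigError

        with pytest.raises(ConfigError, match="no_such.parameter"):
            one_way_dsa(t4_config, TornadoSpec("no_such.parameter", 0.5, 2.0),
                        COMPARISON)


class TestThresholdMultiplier:
    def test_linear_toy_crossing_is_exact(self):
        # ICER(m) = 1000 + 10000 m; crossing WTP 6000 at m = 0.5
        root = bisect_crossing(lambda m: 1000 + 10_000 * m - 6_000, 0.0, 2.0)
        assert root == pytest.approx(0.5, abs=1e-4)

    def test_no_crossing_reported_as_none(self):
        assert bisect_crossing(lambda m: 1.0 + m, 0.0, 2.0) is None

    def test_wtp_at_base_icer_gives_multiplier_one(self, t4_config):
        base = pair_icer(t4_config, COMPARISON)
        m = threshold_multiplier(t4_config,
                                 "strategies.capox_6mo.adjuvant_cost_zar",
                                 COMPARISON, wtp=base, bracket=(0.5, 1.5))
        assert m == pytest.approx(1.0, abs=1e-3)

    def test_threshold_matches_icer_at_returned_multiplier(self, t4_config):
        wtp = t4_config.econ.wtp_per_daly
        path = "strategies.capox_6mo.adjuvant_cost_zar"
        m = threshold_multiplier(t4_config, path, COMPARISON, wtp=wtp)
        assert m is not None
        base = t4_config.get_param(path)
        at_m = pair_icer(t4_config.with_params({path: base * m}), COMPARISON)
        assert at_m == pytest.approx(wtp, rel=5e-3)


class TestRunPsa:
    def fixed_specs(self, config):
        return [DistributionSpec("strategies.capox_3mo.adjuvant_cost_zar",
                                 DistFamily.FIXED,
                                 config.strategies["capox_3mo"].adjuvant_cost_zar)]

    def test_fixed_distributions_degenerate_to_base_case(self, stage2_config,
                                                         stage2_report):
        res = run_psa(stage2_config, self.fixed_specs(stage2_config),
                      PSAConfig(n_iterations=3, rng_seed=0))
        base = {r.strategy: (r.total_cost, r.dalys_averted)
                for r in stage2_report.results}
        for _, row in res.iterations.iterrows():
            c, e = base[row["strategy"]]
            assert row["cost_intl"] == pytest.approx(c, abs=1e-9)
            assert row["dalys_averted"] == pytest.approx(e, abs=1e-12)
        # CEAC is a step function: exactly one optimal strategy per WTP
        for _, grp in res.ceac.groupby("wtp"):
            assert sorted(grp["probability_optimal"]) == [0, 0, 0, 1]

    def test_ceac_rows_sum_to_one_and_seed_reproducibility(self, stage2_config):
        dists = default_psa_distributions(stage2_config)
        res1 = run_psa(stage2_config, dists, PSAConfig(n_iterations=40, rng_seed=5))
        res2 = run_psa(stage2_config, dists, PSAConfig(n_iterations=40, rng_seed=5))
        sums = res1.ceac.groupby("wtp")["probability_optimal"].sum()
        assert np.allclose(sums, 1.0, atol=1e-12)
        assert res1.iterations.equals(res2.iterations)
        assert res1.ceac.equals(res2.ceac)
        assert res1.metadata["config_hash"] == res2.metadata["config_hash"]

    def test_modal_strategy_matches_deterministic_recommendation(
            self, stage2_config, stage2_report):
        res = run_psa(stage2_config, default_psa_distributions(stage2_config),
                      PSAConfig(n_iterations=120, rng_seed=11))
        modal = max(res.optimal_share_at_base_wtp,
                    key=res.optimal_share_at_base_wtp.get)
        assert modal == stage2_report.recommended


class TestSubgroup:
    def test_unit_multipliers_leave_config_unchanged(self, stage2_config):
        sub = subgroup_model(stage2_config, "unit",
                             {k: 1.0 for k in stage2_config.strategies})
        for name in stage2_config.strategies:
            assert np.array_equal(sub.build_schedules(name).p_recur,
                                  stage2_config.build_schedules(name).p_recur)

    def test_elevated_multiplier_weakly_increases_probabilities(self, stage2_config):
        sub = subgroup_model(stage2_config, "hi", {"capox_3mo": 1.5})
        base = stage2_config.build_schedules("capox_3mo").p_recur
        up = sub.build_schedules("capox_3mo").p_recur
        assert np.all(up >= base)
        assert up.sum() > base.sum()

    def test_sufficient_hazard_elevation_flips_recommendation_to_capox6(
            self, stage2_config, stage2_report):
        assert stage2_report.recommended == "capox_3mo"
        t4 = SUBGROUP_MULTIPLIERS["high_risk_stage_ii"]["t4"]
        rec = run_base_case(subgroup_model(stage2_config, "t4", t4)).recommended
        assert rec == "capox_6mo"

    def test_low_risk_subgroups_keep_short_course_optimal(self, stage2_config,
                                                          stage3_config):
        for cfg, sg in ((stage2_config, "t3"), (stage2_config, "lymph_nodes_ge_10"),
                        (stage3_config, "t3n1")):
            mult = SUBGROUP_MULTIPLIERS[cfg.stage][sg]
            assert run_base_case(subgroup_model(cfg, sg, mult)).recommended == "capox_3mo"

    def test_nonpositive_multiplier_rejected(self, stage2_config):
        with pytest.raises(SensitivityError):
            subgroup_model(stage2_config, "bad", {"capox_3mo": 0.0})


class TestScenario:
    def test_config_without_folfiri_is_unchanged(self, stage2_config):
        no_folfiri = stage2_config.with_params({})
        for strat in no_folfiri.strategies.values():
            if strat.first_line_regimen == "FOLFIRI":
                strat.first_line_regimen = "capecitabine"
            if strat.second_line_regimen == "FOLFIRI":
                strat.second_line_regimen = "capecitabine"
        swapped = scenario_xeliri(no_folfiri)
        assert swapped.content_hash() == no_folfiri.content_hash()

    def test_swap_touches_only_folfiri_cost_rows(self, stage3_config):
        swapped = scenario_xeliri(stage3_config)
        for name in stage3_config.strategies:
            base, new = stage3_config.strategies[name], swapped.strategies[name]
            for line in ("first", "second"):
                reg = getattr(base, f"{line}_line_regimen")
                if reg == "FOLFIRI":
                    assert getattr(new, f"{line}_line_regimen") == "XELIRI"
                else:
                    assert getattr(new, f"{line}_line_cost_zar") == \
                        getattr(base, f"{line}_line_cost_zar")
            assert np.array_equal(swapped.recurrence_schedules[name],
                                  stage3_config.recurrence_schedules[name])

    @pytest.mark.parametrize("stage_fixture", ["stage2_config", "stage3_config"])
    def test_capox3_remains_recommended_under_xeliri(self, stage_fixture, request):
        cfg = request.getfixturevalue(stage_fixture)
        assert run_base_case(scenario_xeliri(cfg)).recommended == "capox_3mo"


class TestStartAgeSweep:
    def test_stage_iii_recommendation_stable_from_40_to_80(self, stage3_config):
        for age in (40, 50, 60, 70, 80):
            cfg = stage3_config.with_params({"settings.start_age": age})
            assert run_base_case(cfg).recommended == "capox_3mo", age
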