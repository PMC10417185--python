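"""Currency, discounting, DALY accounting, NMB, and the frontier."""

import itertools

import numpy as np
import pytest

from colcea.config import StrategySpec
from colcea.economics import (
    DisabilityWeights,
    Dominance,
    EconomicsError,
    SharedCosts,
    SurveillanceSchedule,
    compute_dalys,
    convert_currency,
    discount_factors,
    discounted_costs,
    frontier,
    net_monetary_benefit,
)
from colcea.engine import CohortTrace, ModelSettings, STATE_COLUMNS
from colcea.reference import PUBLISHED_BASE_CASE, PUBLISHED_COST_PAIRS_ZAR_TO_INTL


def make_trace(occupancy: np.ndarray, flows: dict | None = None) -> CohortTrace:
    horizon = occupancy.shape[0] - 1
    event_flows = {k: np.zeros(horizon) for k in
                   ("recurrence", "hepatectomy", "first_line", "second_line",
                    "dead_cc", "dead_other")}
    if flows:
        event_flows.update(flows)
    return CohortTrace(
        occupancy=occupancy,
        half_cycle_occupancy=0.5 * (occupancy[:-1] + occupancy[1:]),
        event_flows=event_flows,
        df_background_survival=np.ones(horizon + 1),
    )


def occupancy_in_state(state: str, horizon: int, fraction: float = 1.0) -> np.ndarray:
    occ = np.zeros((horizon + 1, 6))
    occ[:, STATE_COLUMNS.index(state)] = fraction
    occ[:, 0] += 1.0 - fraction
    return occ


def null_strategy(**overrides) -> StrategySpec:
    kwargs = dict(
        name="test", label="test", adjuvant_regimen=None, adjuvant_months=0,
        adjuvant_cost_zar=0.0, first_line_regimen="FOLFIRI", first_line_cost_zar=0.0,
        second_line_regimen="XELIRI", second_line_cost_zar=0.0,
        post_recurrence_stratum="doublet", ae_incidence={},
        residual_neuropathy_incidence=0.0, first_line_visit_days=0,
        second_line_visit_days=0,
    )
    kwargs.update(overrides)
    return StrategySpec(**kwargs)


ZERO_COSTS = SharedCosts(
    hepatectomy_zar=0, bloodwork_zar=0, ct_scan_zar=0, colonoscopy_zar=0,
    ae_event_zar={}, residual_neuropathy_annual_zar=0,
    transport_per_day_zar=0, lost_wages_per_day_zar=0,
)
NO_SURVEILLANCE = SurveillanceSchedule(visits={})
SETTINGS_R0 = ModelSettings(start_age=80, max_age=81, annual_discount_rate=0.0)
SETTINGS_R5 = ModelSettings(start_age=80, max_age=83, annual_discount_rate=0.05)


class TestCurrency:
    def test_zero(self):
        assert convert_currency(0.0) == 0.0

    @pytest.mark.parametrize("zar, intl", PUBLISHED_COST_PAIRS_ZAR_TO_INTL)
    def test_published_cost_pairs(self, zar, intl):
        assert convert_currency(zar, display=True) == intl

    def test_internal_value_is_unrounded(self):
        assert convert_currency(9_748.0) == pytest.approx(9_748.0 / 7.097)

    def test_negative_rejected(self):
        with pytest.raises(EconomicsError):
            convert_currency(-1.0)


class TestDiscountedCosts:
    def test_zero_cost_table_gives_zero(self):
        trace = make_trace(occupancy_in_state("DISEASE_FREE", 12))
        total = discounted_costs(trace, null_strategy(), ZERO_COSTS,
                                 NO_SURVEILLANCE, SETTINGS_R5)
        assert total == 0.0

    def test_one_time_cost_at_cycle_zero_is_undiscounted(self):
        horizon = 12
        flows = {"first_line": np.zeros(horizon)}
        flows["first_line"][0] = 1.0
        trace = make_trace(occupancy_in_state("REC_FIRST_LINE", horizon), flows)
        strat = null_strategy(first_line_cost_zar=7.097 * 1000.0)
        total = discounted_costs(trace, strat, ZERO_COSTS, NO_SURVEILLANCE, SETTINGS_R5)
        assert total == pytest.approx(1000.0, abs=1e-9)

    def test_cost_at_cycle_12_discounted_by_one_annual_factor(self):
        horizon = 24
        flows = {"first_line": np.zeros(horizon)}
        flows["first_line"][12] = 1.0
        trace = make_trace(occupancy_in_state("REC_FIRST_LINE", horizon), flows)
        strat = null_strategy(first_line_cost_zar=7.097 * 1000.0)
        total = discounted_costs(trace, strat, ZERO_COSTS, NO_SURVEILLANCE, SETTINGS_R5)
        assert total == pytest.approx(1000.0 / 1.05, abs=1e-9)

    def test_zero_rate_reproduces_undiscounted_sum(self):
        horizon = 12
        flows = {"first_line": np.zeros(horizon), "second_line": np.zeros(horizon)}
        flows["first_line"][3] = 0.5
        flows["second_line"][9] = 0.25
        trace = make_trace(occupancy_in_state("REC_FIRST_LINE", horizon), flows)
        strat = null_strategy(first_line_cost_zar=7.097 * 100.0,
                              second_line_cost_zar=7.097 * 200.0)
        total = discounted_costs(trace, strat, ZERO_COSTS, NO_SURVEILLANCE, SETTINGS_R0)
        assert total == pytest.approx(0.5 * 100 + 0.25 * 200, abs=1e-9)

    def test_missing_ae_cost_row_raises_named_error(self):
        trace = make_trace(occupancy_in_state("DISEASE_FREE", 12))
        strat = null_strategy(adjuvant_months=3, adjuvant_cost_zar=100.0,
                              ae_incidence={"diarrhea": 0.1})
        with pytest.raises(EconomicsError, match="diarrhea"):
            discounted_costs(trace, strat, ZERO_COSTS, NO_SURVEILLANCE, SETTINGS_R5)


class TestComputeDalys:
    def test_no_recurrence_or_cancer_death_gives_zero(self):
        trace = make_trace(occupancy_in_state("DISEASE_FREE", 24))
        yll, yld, daly = compute_dalys(trace, null_strategy(),
                                       DisabilityWeights(), SETTINGS_R5)
        assert (yll, yld, daly) == (0.0, 0.0, 0.0)

    def test_full_cohort_dead_of_cancer_accrues_one_yll_per_year(self):
        trace = make_trace(occupancy_in_state("DEAD_CC", 12))
        yll, yld, daly = compute_dalys(trace, null_strategy(),
                                       DisabilityWeights(), SETTINGS_R0)
        assert yll == pytest.approx(1.0, abs=1e-12)
        assert yld == 0.0

    def test_half_cohort_recurrent_for_a_year(self):
        trace = make_trace(occupancy_in_state("REC_FIRST_LINE", 12, fraction=0.5))
        _, yld, _ = compute_dalys(trace, null_strategy(),
                                  DisabilityWeights(), SETTINGS_R0)
        assert yld == pytest.approx(0.2255, abs=1e-12)

    def test_background_death_accrues_nothing(self):
        trace = make_trace(occupancy_in_state("DEAD_OTHER", 24))
        _, _, daly = compute_dalys(trace, null_strategy(),
                                   DisabilityWeights(), SETTINGS_R0)
        assert daly == 0.0


class TestNetMonetaryBenefit:
    def test_zero_effect_is_negative_cost(self):
        assert net_monetary_benefit(2_693.0, 0.0, 13_764.0) == -2_693.0

    def test_break_even(self):
        assert net_monetary_benefit(13_764.0, 1.0, 13_764.0) == 0.0

    def test_published_stage_iii_values(self):
        nmb = net_monetary_benefit(5_279.0, 5.46, 13_764.0)
        assert nmb == pytest.approx(69_872.44)


class TestFrontier:
    def test_single_strategy_is_reference_without_icer(self):
        (res,) = frontier([("only", 100.0, 0.0)], wtp=10_000.0)
        assert res.dominance is Dominance.REFERENCE
        assert res.icer is None
        assert res.recommended

    def test_published_stage_ii_classification(self):
        vals = PUBLISHED_BASE_CASE["high_risk_stage_ii"]
        results = {r.strategy: r for r in frontier(
            [(k, c, e) for k, (c, e) in vals.items()], wtp=13_764.0)}
        assert results["cape_6mo"].dominance is Dominance.EXTENDED_DOMINATED
        assert results["capox_3mo"].icer == pytest.approx(250.0)
        assert results["capox_6mo"].icer > 13_764.0
        assert results["capox_3mo"].recommended

    def test_published_stage_ii_icer_after_recomputation_convention(self):
        vals = PUBLISHED_BASE_CASE["high_risk_stage_ii"]
        results = {r.strategy: r for r in frontier(
            [(k, c, e) for k, (c, e) in vals.items()], wtp=13_764.0,
            recompute_after_extended=True)}
        # vs the reference directly once the extended-dominated arm is dropped
        assert results["capox_3mo"].icer == pytest.approx((4083 - 2693) / 2.21, rel=1e-9)

    def test_published_stage_iii_classification(self):
        vals = PUBLISHED_BASE_CASE["stage_iii"]
        results = {r.strategy: r for r in frontier(
            [(k, c, e) for k, (c, e) in vals.items()], wtp=13_764.0)}
        assert results["no_adjuvant"].dominance is Dominance.DOMINATED
        assert results["capox_6mo"].dominance is Dominance.DOMINATED
        assert results["capox_3mo"].icer == pytest.approx(1042.0, abs=0.2)
        assert results["capox_3mo"].recommended

    def test_dominated_strategies_never_carry_an_icer(self):
        vals = PUBLISHED_BASE_CASE["stage_iii"]
        for r in frontier([(k, c, e) for k, (c, e) in vals.items()], wtp=13_764.0):
            if r.dominance is Dominance.DOMINATED:
                assert r.icer is None

    def test_order_invariance(self):
        vals = list(PUBLISHED_BASE_CASE["high_risk_stage_ii"].items())
        baseline = None
        for perm in itertools.permutations(vals):
            res = frontier([(k, c, e) for k, (c, e) in perm], wtp=13_764.0)
            summary = sorted((r.strategy, r.dominance, r.icer, r.recommended)
                             for r in res)
            if baseline is None:
                baseline = summary
            assert summary == baseline

    def test_nmb_identity_and_agreement_with_recommendation(self):
        for stage, vals in PUBLISHED_BASE_CASE.items():
            res = frontier([(k, c, e) for k, (c, e) in vals.items()], wtp=13_764.0)
            for r in res:
                assert r.nmb == 13_764.0 * r.dalys_averted - r.total_cost
            nmb_best = max(res, key=lambda r: r.nmb)
            assert nmb_best.recommended

    def test_tied_costs_broken_by_effectiveness(self):
        res = frontier([("a", 100.0, 1.0), ("b", 100.0, 2.0)], wtp=1_000.0)
        by_name = {r.strategy: r for r in res}
        assert by_name["a"].dominance is Dominance.DOMINATED
        assert by_name["b"].recommended


def test_discount_factors_zero_rate_is_identity():
    assert np.all(discount_factors(30, 0.0) == 1.0)
    assert discount_factors(13, 0.05)[12] == pytest.approx(1 / 1.05)
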