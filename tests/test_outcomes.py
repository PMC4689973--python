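"""Discounting, cost components, QALY/LY accounting, 10-year risks."""

import numpy as np
import pytest

import osteocea as oc
from osteocea.markov import N_STATES, STATE_INDEX, CohortTrace
from osteocea.outcomes import (
    DAYS_PER_CYCLE,
    StrategyTotals,
    cycle_costs,
    cycle_qalys,
    discount_factor,
    ltc_occupancy,
)
from osteocea.treatment import SubcohortProfile


class TestDiscountFactor:
    @pytest.mark.parametrize(
        "cycle,rate,expected",
        [(0, 0.03, 1.0), (5, 0.0, 1.0), (2, 0.03, 1 / 1.03), (4, 0.03, 1 / 1.03**2)],
    )
    def test_values(self, cycle, rate, expected):
        assert discount_factor(cycle, rate) == pytest.approx(expected, abs=1e-12)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            discount_factor(1, -0.01)


def _static_trace(cfg, state: str, n=None) -> CohortTrace:
    """A trace pinned to one state with no events (accounting unit tests)."""
    n = cfg.n_cycles if n is None else n
    occ = np.zeros((n + 1, N_STATES))
    occ[:, STATE_INDEX[state]] = 1.0
    return CohortTrace(occupancy=occ, events=np.zeros((n, 3)))


ON_TREATMENT = SubcohortProfile("completer", stop_cycle=10, weight=1.0, offset_years=2.0)
NEVER_TREATED = SubcohortProfile("dropout", stop_cycle=0, weight=1.0, offset_years=0.0)


class TestCycleCosts:
    def test_denosumab_on_treatment_full_year(self, base_cfg):
        """One treated year, no events: drug + physician + 2 nurse visits + half a BMD."""
        den = base_cfg.strategy("denosumab")
        trace = _static_trace(base_cfg, "well")
        total = {}
        for cycle in (1, 2):
            for k, v in cycle_costs(trace, den, ON_TREATMENT, base_cfg, cycle).items():
                total[k] = total.get(k, 0.0) + v
        assert total["drug"] == pytest.approx(1650)
        assert total["admin_monitoring"] == pytest.approx(100 + 2 * 42 + 243 / 2)
        assert total["fracture_year1"] == total["long_term_care"] == 0.0

    def test_costs_stop_at_discontinuation(self, base_cfg):
        den = base_cfg.strategy("denosumab")
        trace = _static_trace(base_cfg, "well")
        out = cycle_costs(trace, den, NEVER_TREATED, base_cfg, 1)
        assert out["drug"] == out["admin_monitoring"] == 0.0

    def test_incident_hip_event_costed_once(self, base_cfg):
        den = base_cfg.strategy("denosumab")
        trace = _static_trace(base_cfg, "well")
        trace.events[0, 0] = 0.01  # 1% incident hip fractures in cycle 1
        out1 = cycle_costs(trace, den, ON_TREATMENT, base_cfg, 1)
        assert out1["fracture_year1"] == pytest.approx(0.01 * 28112)  # 281.12
        # the event does not recur in the next cycle
        out2 = cycle_costs(trace, den, ON_TREATMENT, base_cfg, 2)
        assert out2["fracture_year1"] == 0.0

    def test_posthip_occupancy_accrues_subsequent_cost(self, base_cfg):
        den = base_cfg.strategy("denosumab")
        trace = _static_trace(base_cfg, "post_hip")
        out = cycle_costs(trace, den, NEVER_TREATED, base_cfg, 1)
        assert out["fracture_subsequent"] == pytest.approx(9734 / 2)

    def test_ltc_pool_fed_by_admission_fraction(self, base_cfg):
        trace = _static_trace(base_cfg, "post_hip")
        trace.events[0, 0] = 0.10
        pool = ltc_occupancy(trace, base_cfg)
        assert pool[0] == 0.0
        assert pool[1] == pytest.approx(0.10 * base_cfg.costs.ltc_admission_fraction)
        # the pool persists (shrinking only with mortality) and is costed daily
        assert 0 < pool[2] <= pool[1]
        den = base_cfg.strategy("denosumab")
        out = cycle_costs(trace, den, NEVER_TREATED, base_cfg, 1, pool)
        assert out["long_term_care"] == pytest.approx(236 * DAYS_PER_CYCLE * pool[1])


class TestCycleQalys:
    @pytest.mark.parametrize(
        "state,mult", [("well", 1.0), ("hip_y1a", 0.700), ("vert_y1b", 0.590), ("post_vert", 0.930)]
    )
    def test_state_multipliers(self, base_cfg, state, mult):
        trace = _static_trace(base_cfg, state)
        u = base_cfg.utilities.baseline(78)
        assert cycle_qalys(trace, base_cfg, 1) == pytest.approx(0.5 * u * mult)

    def test_dead_accrues_nothing(self, base_cfg):
        trace = _static_trace(base_cfg, "dead")
        assert cycle_qalys(trace, base_cfg, 1) == 0.0


class TestAccumulate:
    def test_immortal_cohort_two_cycles_one_ly(self, cfg):
        cfg.run_settings.annual_discount_rate_effects = 0.0
        cfg.run_settings.annual_discount_rate_costs = 0.0
        trace = _static_trace(cfg, "well", n=cfg.n_cycles)
        den = cfg.strategy("denosumab")
        sub = SubcohortProfile("completer", stop_cycle=0, weight=1.0, offset_years=0.0)
        # restrict to 2 cycles by zeroing occupancy afterwards
        trace.occupancy[3:] = 0.0
        trace.occupancy[3:, STATE_INDEX["dead"]] = 1.0
        totals = oc.accumulate([(sub, trace)], den, cfg)
        first_year_lys = 0.5 * (trace.alive(1) + trace.alive(2))
        assert first_year_lys == 1.0
        assert totals.lys == pytest.approx(1.0)

    def test_components_sum_to_total(self, base_totals):
        for t in base_totals:
            assert sum(t.components.values()) == pytest.approx(t.cost, abs=1e-6)
            assert t.qalys <= t.lys
            assert t.cost >= 0 and t.qalys >= 0

    def test_doubling_unit_costs_doubles_total(self, two_strategy_cfg):
        cfg = two_strategy_cfg.model_copy(deep=True)
        base = oc.run_strategy(cfg, cfg.strategy("denosumab"))
        c = cfg.costs
        c.fracture_year1 = {k: 2 * v for k, v in c.fracture_year1.items()}
        c.hip_subsequent_annual *= 2
        c.ltc_daily *= 2
        c.monitoring = [
            m.model_copy(update={"unit_cost": 2 * m.unit_cost}) for m in c.monitoring
        ]
        den = cfg.strategy("denosumab")
        den.annual_drug_cost *= 2
        den.admin_events = [
            m.model_copy(update={"unit_cost": 2 * m.unit_cost}) for m in den.admin_events
        ]
        doubled = oc.run_strategy(cfg, den)
        assert doubled.cost == pytest.approx(2 * base.cost, rel=1e-12)
        assert doubled.qalys == pytest.approx(base.qalys, rel=1e-12)

    def test_ten_year_risk_matches_trace_export(self, base_cfg):
        """10-year risks equal the brute-force event sum from the tidy export."""
        alen = base_cfg.strategy("generic_alendronate")
        traces = oc.strategy_traces(base_cfg, alen)
        totals = oc.accumulate(traces, alen, base_cfg)
        agg = oc.aggregate_trace(traces)
        ev = agg.events_frame()
        for site in oc.SITES:
            brute = ev[(ev["site"] == site) & (ev["cycle"] <= 20)]["incident_fraction"].sum()
            assert totals.ten_year_risk[site] == pytest.approx(brute, abs=1e-12)

    def test_qalys_equal_lys_when_all_utilities_one(self, two_strategy_cfg):
        cfg = two_strategy_cfg.model_copy(deep=True)
        cfg.utilities.baseline_by_age = {a: 1.0 for a in cfg.utilities.baseline_by_age}
        cfg.utilities.multiplier_year1 = {"hip": 1.0, "vertebral": 1.0, "nhnv": 1.0}
        cfg.utilities.multiplier_later = {"hip": 1.0, "vertebral": 1.0, "nhnv": 1.0}
        for t in oc.run_all(cfg):
            assert t.qalys == pytest.approx(t.lys, rel=1e-12)

    def test_discounting_never_increases_totals(self, two_strategy_cfg):
        cfg = two_strategy_cfg.model_copy(deep=True)
        cfg.run_settings.annual_discount_rate_costs = 0.0
        cfg.run_settings.annual_discount_rate_effects = 0.0
        undiscounted = oc.run_strategy(cfg, cfg.strategy("denosumab"))
        discounted = oc.run_strategy(two_strategy_cfg, two_strategy_cfg.strategy("denosumab"))
        assert discounted.cost < undiscounted.cost
        assert discounted.qalys < undiscounted.qalys

    def test_zero_incidence_equalises_qalys_and_zeroes_fracture_costs(self, cfg):
        for band in cfg.epidemiology.bands:
            band.rates = {"hip": 0.0, "vertebral": 0.0, "nhnv": 0.0}
        totals = oc.run_all(cfg)
        qalys = {t.qalys for t in totals}
        assert max(qalys) - min(qalys) < 1e-12
        for t in totals:
            assert t.components["fracture_year1"] == 0.0
            assert t.components["fracture_subsequent"] == 0.0
            assert t.components["long_term_care"] == 0.0


def test_strategy_totals_dataclass_round_trip():
    t = StrategyTotals("x", cost=10.0, qalys=1.0, lys=2.0)
    assert t.components == {} and t.ten_year_risk == {}
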