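import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from htnsim import (ModelParams, Thresholds, budget_impact, compare,
                    compute_dalys, discount, make_flat_world, simulate_arm,
                    threshold_analysis)
from htnsim.config import ScenarioSpec
from htnsim.economics import (CLASS_COST_SAVING, CLASS_DOMINATED,
                              CLASS_HIGHLY_CE, CLASS_NOT_CE, CEResult,
                              DALYResult, EconResult, accrue_costs)
from htnsim.engine import HealthState
from htnsim.synthetic_data import FixtureSpec


def _econ(label, cost, dalys, n=100, events=10, deaths=5):
    return EconResult(label=label, n=n, horizon_months=240,
                      cost_components={"all": cost},
                      dalys=DALYResult(yld=dalys, yll=0.0,
                                       medication_disutility=0.0),
                      events=events, deaths=deaths, cvd_deaths=deaths)


class TestDiscount:
    def test_zero_rate_is_plain_sum(self):
        stream = np.array([10.0, 20.0, 30.0])
        assert discount(stream, 0.0) == pytest.approx(60.0)

    def test_single_amount_at_time_zero_unchanged(self):
        stream = np.zeros(240)
        stream[0] = 123.45
        assert discount(stream, 0.03) == pytest.approx(123.45)

    def test_constant_stream_matches_geometric_series(self):
        # scalar oracle: sum of c * v^k with v = 1.03^(-1/12)
        c, T = 7.5, 240
        v = 1.03 ** (-1 / 12)
        expected = c * (1 - v ** T) / (1 - v)
        assert discount(np.full(T, c), 0.03) == pytest.approx(expected, rel=1e-12)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            discount(np.ones(3), -0.01)

    @given(rate1=st.floats(0.0, 0.2), rate2=st.floats(0.0, 0.2))
    @settings(max_examples=50, deadline=None)
    def test_present_value_decreases_with_rate(self, rate1, rate2):
        stream = np.ones(120)
        if rate1 < rate2:
            assert discount(stream, rate1) > discount(stream, rate2)


class TestAccrueCosts:
    def _flat_arm(self, **kw):
        world = make_flat_world(FixtureSpec(cohort_size=50, horizon_months=24,
                                            **kw))
        sc = world.config.scenarios["untreated"]
        arm = simulate_arm(world.config, sc, 2, cohort=world.cohort)
        return world, arm

    def test_event_free_untreated_world_accrues_only_programmatic_cost(self):
        world, arm = self._flat_arm(monthly_event_prob=0.0)
        streams = accrue_costs(arm.sim, world.config.costs, world.config.ladder,
                               arm.scenario)
        n = arm.sim.n
        np.testing.assert_allclose(streams.programmatic,
                                   np.full(24, n * 0.13 / 12))
        assert streams.antihypertensive.sum() == 0
        assert streams.acute.sum() == 0 and streams.chronic.sum() == 0

    def test_each_mi_event_costs_inpatient_rate_at_its_cycle(self):
        world, arm = self._flat_arm(monthly_event_prob=0.02, p_mi_given_event=1.0)
        streams = accrue_costs(arm.sim, world.config.costs, world.config.ladder,
                               arm.scenario)
        np.testing.assert_allclose(streams.acute, arm.sim.events_mi * 1040.0)
        assert arm.sim.events_mi.sum() > 0

    def test_drug_stream_totals_annual_cost_for_one_treated_year(self, bundle):
        # arithmetic oracle: one person on step-1 public drugs for 12 months
        from htnsim.engine import SimulationResult
        import pandas as pd
        T = 12
        sim = SimulationResult(
            horizon=T, n=1, occupancy=np.tile([1, 0, 0, 0, 0, 0, 0], (T, 1)),
            acute_first_mi=np.zeros(T, int), acute_first_stroke=np.zeros(T, int),
            acute_multi=np.zeros(T, int), events_mi=np.zeros(T, int),
            events_stroke=np.zeros(T, int),
            treated_counts=np.tile(
                np.array([[0, 0], [1, 0], [0, 0], [0, 0]])[None, :, :], (T, 1, 1)),
            treated_total=np.ones(T, int),
            chronic_counts=np.zeros((T, 4, 2), int),
            initiations=np.zeros(T, int),
            event_log=pd.DataFrame(columns=["cycle", "individual", "type",
                                            "event_number", "first"]),
            death_log=pd.DataFrame(columns=["cycle", "individual", "cause",
                                            "age", "sex"]))
        cfg = bundle.costs.model_copy()
        cfg.opd_visits_per_year = 0.0
        sc = ScenarioSpec(coverage=1, adherence=1)
        streams = accrue_costs(sim, cfg, bundle.ladder, sc)
        d = bundle.ladder[1].annual_cost_public
        assert streams.antihypertensive.sum() == pytest.approx(d)

    def test_component_streams_sum_to_total(self, small_bundle):
        arm = simulate_arm(small_bundle, small_bundle.scenarios["seventy"], 4)
        streams = accrue_costs(arm.sim, small_bundle.costs, small_bundle.ladder,
                               arm.scenario)
        total = sum(streams.components().values())
        np.testing.assert_allclose(streams.total, total)
        assert discount(streams.total, 0.03) == pytest.approx(
            sum(discount(v, 0.03) for v in streams.components().values()))


class TestComputeDalys:
    def test_no_morbidity_no_deaths_no_dalys(self, bundle):
        world = make_flat_world(FixtureSpec(cohort_size=30, horizon_months=36,
                                            monthly_event_prob=0.0))
        arm = simulate_arm(world.config, world.config.scenarios["untreated"], 1,
                          cohort=world.cohort)
        d = compute_dalys(arm.sim, bundle.disability_weights, bundle.lifetable,
                          0.03)
        assert d.total == 0.0

    def test_chronic_year_yields_disability_weight(self, bundle):
        # one person-year in the post-MI state at 0% discount = 0.08 YLD
        import pandas as pd
        from htnsim.engine import SimulationResult
        T = 12
        occ = np.zeros((T, 7), int)
        occ[:, int(HealthState.POST_MI)] = 1
        sim = SimulationResult(
            horizon=T, n=1, occupancy=occ,
            acute_first_mi=np.zeros(T, int), acute_first_stroke=np.zeros(T, int),
            acute_multi=np.zeros(T, int), events_mi=np.zeros(T, int),
            events_stroke=np.zeros(T, int),
            treated_counts=np.zeros((T, 4, 2), int),
            treated_total=np.zeros(T, int),
            chronic_counts=np.zeros((T, 4, 2), int),
            initiations=np.zeros(T, int),
            event_log=pd.DataFrame(columns=["cycle", "individual", "type",
                                            "event_number", "first"]),
            death_log=pd.DataFrame(columns=["cycle", "individual", "cause",
                                            "age", "sex"]))
        d = compute_dalys(sim, bundle.disability_weights, bundle.lifetable, 0.0)
        assert d.yld == pytest.approx(0.08)
        assert d.yll == 0.0

    def test_death_yields_residual_life_expectancy_at_zero_discount(self, bundle):
        import pandas as pd
        from htnsim.engine import SimulationResult
        T = 2
        sim = SimulationResult(
            horizon=T, n=1, occupancy=np.tile([0, 0, 0, 0, 0, 0, 1], (T, 1)),
            acute_first_mi=np.zeros(T, int), acute_first_stroke=np.zeros(T, int),
            acute_multi=np.zeros(T, int), events_mi=np.zeros(T, int),
            events_stroke=np.zeros(T, int),
            treated_counts=np.zeros((T, 4, 2), int),
            treated_total=np.zeros(T, int),
            chronic_counts=np.zeros((T, 4, 2), int),
            initiations=np.zeros(T, int),
            event_log=pd.DataFrame(columns=["cycle", "individual", "type",
                                            "event_number", "first"]),
            death_log=pd.DataFrame([{"cycle": 1, "individual": 0,
                                     "cause": "cvd", "age": 52.0, "sex": 1}]))
        d = compute_dalys(sim, bundle.disability_weights, bundle.lifetable, 0.0)
        # lifetable oracle: male aged 52 falls in the 50-55 band
        expected = bundle.lifetable.male[2]
        assert d.yll == pytest.approx(expected)

    def test_medication_disutility_only_when_enabled(self, small_bundle):
        arm = simulate_arm(small_bundle, small_bundle.scenarios["seventy"], 4)
        off = compute_dalys(arm.sim, small_bundle.disability_weights,
                            small_bundle.lifetable, 0.03, False)
        on = compute_dalys(arm.sim, small_bundle.disability_weights,
                           small_bundle.lifetable, 0.03, True)
        assert off.medication_disutility == 0.0
        assert on.medication_disutility > 0.0
        assert on.yld == off.yld and on.yll == off.yll


class TestCompare:
    def test_cost_saving_has_no_icer(self):
        ce = compare(_econ("i", 95, 8.0), _econ("c", 100, 10.0))
        assert ce.classification == CLASS_COST_SAVING and ce.icer is None

    def test_highly_cost_effective_below_half_gdp(self):
        ce = compare(_econ("i", 200, 9.0), _econ("c", 100, 10.0))
        assert ce.icer == pytest.approx(100.0)
        assert ce.classification == CLASS_HIGHLY_CE

    def test_not_cost_effective_above_gdp(self):
        ce = compare(_econ("i", 3000, 9.0), _econ("c", 100, 10.0))
        assert ce.icer == pytest.approx(2900.0)
        assert ce.classification == CLASS_NOT_CE

    def test_degenerate_zero_deltas_dominated_without_division(self):
        ce = compare(_econ("i", 100, 10.0), _econ("c", 100, 10.0))
        assert ce.classification == CLASS_DOMINATED and ce.icer is None

    def test_dominated_when_no_dalys_averted_at_extra_cost(self):
        ce = compare(_econ("i", 150, 11.0), _econ("c", 100, 10.0))
        assert ce.classification == CLASS_DOMINATED and ce.icer is None

    def test_label_exchange_flips_delta_signs(self):
        a, b = _econ("a", 130, 9.0), _econ("b", 100, 10.0)
        ab, ba = compare(a, b), compare(b, a)
        assert ab.delta_cost == pytest.approx(-ba.delta_cost)
        assert ab.dalys_averted == pytest.approx(-ba.dalys_averted)


class TestBudgetImpact:
    def _ce(self, delta, n=100, horizon=240):
        return CEResult(intervention="i", comparator="c", n=n,
                        horizon_months=horizon, delta_cost=delta,
                        delta_components={"all": delta}, dalys_averted=1.0,
                        dalys_averted_pct=0.1, events_averted_pct=0.1,
                        deaths_averted_pct=0.1, icer=None,
                        classification=CLASS_COST_SAVING,
                        thresholds=Thresholds(), intervention_total_cost=1000)

    def test_zero_delta_zero_expenditure(self):
        bi = budget_impact(self._ce(0.0), 267.4e6)
        assert bi.annual_net_expenditure == 0.0

    def test_linear_in_population(self):
        a = budget_impact(self._ce(-500.0), 100e6)
        b = budget_impact(self._ce(-500.0), 200e6)
        assert b.annual_net_expenditure == pytest.approx(
            2 * a.annual_net_expenditure)

    def test_scalar_example(self):
        # per-capita -$0.10/yr on 267.4 mn people => -$26.74 mn per year
        ce = self._ce(delta=-0.10 * 100 * 20, n=100, horizon=240)
        bi = budget_impact(ce, 267.4e6)
        assert bi.annual_net_expenditure == pytest.approx(-26.74e6)

    def test_zero_cohort_rejected(self):
        with pytest.raises(ValueError):
            budget_impact(self._ce(1.0, n=0), 1e6)


class TestThresholdAnalysis:
    def _ce(self, delta_cost, dalys, base_cost, n=1):
        return CEResult(intervention="i", comparator="c", n=n,
                        horizon_months=240, delta_cost=delta_cost,
                        delta_components={}, dalys_averted=dalys,
                        dalys_averted_pct=0.0, events_averted_pct=0.0,
                        deaths_averted_pct=0.0, icer=None,
                        classification=CLASS_COST_SAVING,
                        thresholds=Thresholds(),
                        intervention_total_cost=base_cost)

    def test_closed_form_surcharge(self):
        # (-10 + 100 s) / 1 = 1169  =>  s = 11.79%
        ce = self._ce(-10.0, 1.0, 100.0)
        s = threshold_analysis(ce, threshold=1169.0)
        assert s == pytest.approx(100 * (1169 + 10) / 100, rel=1e-9)

    def test_zero_threshold_gives_cost_saving_margin(self):
        ce = self._ce(-10.0, 1.0, 100.0)
        s = threshold_analysis(ce, threshold=0.0)
        assert s == pytest.approx(10.0)  # surcharge consuming the saving

    def test_unbounded_threshold_flagged(self):
        ce = self._ce(-10.0, 1.0, 100.0)
        assert threshold_analysis(ce, threshold=np.inf) == np.inf

    def test_already_beyond_threshold_returns_zero(self):
        ce = self._ce(5000.0, 1.0, 100.0)
        assert threshold_analysis(ce, threshold=1169.0) == 0.0

    def test_monotone_in_threshold(self):
        ce = self._ce(-10.0, 1.0, 100.0)
        assert threshold_analysis(ce, threshold=2338.0) > \
            threshold_analysis(ce, threshold=1169.0)
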