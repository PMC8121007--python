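"""Default model inputs and miniature oracle worlds.

:func:`make_default_config` assembles the package's default
:class:`~htnsim.config.ConfigBundle`: every point-valued input (cascade
baselines, acute/chronic recurrence risks, unit costs, disability weights,
discounting, thresholds) at its published estimate, and every age/sex- or
SBP-banded quantity expanded into a lookup table spanning its published
range.  The banded interiors and the cardiovascular risk surface are
synthetic calibrations — documented, plausible for Indian adults, and fully
replaceable via config.

:func:`make_flat_world` builds degenerate worlds with age/sex-independent
probabilities whose expected behaviour has a closed form (a cohort Markov
chain), so the microsimulation can be verified against matrix-power oracles.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Dict

import numpy as np
from pydantic import BaseModel, Field

from .config import (AgeBandTable, CascadeConfig, ConfigBundle, CostConfig,
                     DisabilityWeightsConfig, EconomicsConfig,
                     EventSplitConfig, LadderStep, ParameterDistribution,
                     PopulationConfig, RiskModelConfig, ScenarioSpec,
                     SexParams, TrajectoryConfig, TransitionConfig)
from .population import Cohort, generate_cohort

# 5-year age bands from 40 to 110 (the oldest age reachable in a 40-year run)
_EDGES = [float(a) for a in range(40, 115, 5)]
_NB = len(_EDGES) - 1  # 14 bands


def _geom(lo: float, hi: float, n: int, hold_from: int | None = None) -> list[float]:
    """Geometric ramp from lo to hi over the first ``hold_from`` bands, then flat."""
    stop = hold_from if hold_from is not None else n
    ramp = list(np.geomspace(lo, hi, stop))
    return [float(v) for v in ramp + [hi] * (n - stop)]


def _lin(lo: float, hi: float, n: int) -> list[float]:
    return [float(v) for v in np.linspace(lo, hi, n)]


def _bilinear_rr(best: float, worst: float, n_age: int = 4,
                 n_sbp: int = 3) -> list[list[float]]:
    """RR table: strongest effect (lowest RR) young & high-SBP, weakest old & low-SBP."""
    table = []
    for ai in range(n_age):
        row = []
        a = ai / (n_age - 1)
        for si in range(n_sbp):
            s = si / (n_sbp - 1)
            w = ((1 - a) + s) / 2.0
            row.append(round(worst + (best - worst) * w, 4))
        table.append(row)
    return table


def make_default_config() -> ConfigBundle:
    """The package's default input set (see module docstring)."""
    population = PopulationConfig(
        cohort_size=10_000,
        age_range=(40.0, 69.0),
        female=SexParams(sbp_mean=126.0, sbp_sd=18.0, sbp_bounds=(80.0, 240.0),
                         bmi_mean=24.1, bmi_sd=4.5, smoking_prev=0.05),
        male=SexParams(sbp_mean=129.0, sbp_sd=17.0, sbp_bounds=(80.0, 240.0),
                       bmi_mean=23.3, bmi_sd=4.0, smoking_prev=0.32),
        target_hypertension_prevalence=0.33,
    )

    risk_model = RiskModelConfig(
        baseline=AgeBandTable(
            edges=_EDGES,
            female=_lin(0.018, 0.32, _NB),
            male=_lin(0.025, 0.40, _NB)),
        coef_sbp=0.016, coef_bmi=0.015, coef_smoker=0.30,
        ref_sbp=130.0, ref_bmi=24.0)

    event_split = EventSplitConfig(p_mi=AgeBandTable(
        edges=_EDGES,
        female=_lin(0.550, 0.376, _NB),
        male=_lin(0.667, 0.450, _NB)))

    treatment_effect_ihd = _bilinear_rr(best=0.32, worst=0.89)
    treatment_effect_stroke = _bilinear_rr(best=0.20, worst=0.89)

    transitions = TransitionConfig(
        mi_30d_fatality=AgeBandTable(
            edges=_EDGES,
            female=_lin(0.012, 0.13, _NB),
            male=_lin(0.010, 0.13, _NB)),
        stroke_30d_fatality_female=0.12,
        stroke_30d_fatality_male=0.13,
        ihd_monthly_mortality=AgeBandTable(
            edges=_EDGES,
            female=_lin(0.001, 0.018, _NB),
            male=_lin(0.001, 0.019, _NB)),
        stroke_monthly_mortality=AgeBandTable(
            edges=_EDGES,
            female=_lin(0.001, 0.012, _NB),
            male=_lin(0.001, 0.013, _NB)),
        non_cvd_death_annual=AgeBandTable(
            edges=_EDGES,
            female=_geom(0.005, 0.176, _NB, hold_from=11),
            male=_geom(0.006, 0.176, _NB, hold_from=10)),
    )

    ladder = [
        LadderStep(step=0, sbp_min=0.0, annual_cost_public=0.0,
                   annual_cost_private=0.0),
        LadderStep(step=1, sbp_min=140.0, annual_cost_public=0.88,
                   annual_cost_private=5.42),
        LadderStep(step=2, sbp_min=160.0, annual_cost_public=3.97,
                   annual_cost_private=26.04),
        LadderStep(step=3, sbp_min=180.0, annual_cost_public=17.90,
                   annual_cost_private=125.14),
    ]

    lifetable = AgeBandTable(
        edges=_EDGES,
        female=[37.1, 32.8, 28.6, 24.6, 20.7, 17.0, 13.6, 10.5, 7.9, 5.8,
                4.3, 3.2, 2.4, 1.9],
        male=[34.3, 30.1, 26.0, 22.1, 18.5, 15.1, 12.0, 9.3, 7.0, 5.2,
              3.9, 3.0, 2.3, 1.8])

    scenarios = {
        "status_quo": ScenarioSpec(label="status_quo", coverage=0.17,
                                   adherence=0.30, protocol="NPCDCS",
                                   programmatic_cost_on=False),
        "seventy": ScenarioSpec(label="seventy", coverage=0.70, adherence=0.70,
                                protocol="IHCI_simplified"),
    }

    def beta(name, target, point, lo, hi):
        return ParameterDistribution(name=name, target=target, point=point,
                                     lower95=lo, upper95=hi, family="beta")

    psa = [
        beta("reinfarction_30d", "transitions.reinfarction_30d",
             0.0120, 0.0099, 0.0141),
        beta("stroke_after_mi_30d", "transitions.stroke_after_mi_30d",
             0.0060, 0.0045, 0.0075),
        beta("repeat_stroke_30d", "transitions.repeat_stroke_30d",
             0.15, 0.10, 0.20),
        beta("chronic_ihd_reinfarction", "transitions.chronic_ihd_reinfarction",
             0.079, 0.073, 0.085),
        beta("chronic_ihd_stroke", "transitions.chronic_ihd_stroke",
             0.014, 0.012, 0.016),
        beta("chronic_stroke_mi", "transitions.chronic_stroke_mi",
             0.043, 0.038, 0.048),
        beta("chronic_stroke_stroke", "transitions.chronic_stroke_stroke",
             0.037, 0.033, 0.041),
        beta("dw_medication_daily", "disability_weights.medication_daily",
             0.049, 0.031, 0.072),
        beta("dw_acute_mi", "disability_weights.acute_mi", 0.432, 0.288, 0.579),
        beta("dw_acute_stroke", "disability_weights.acute_stroke",
             0.570, 0.377, 0.707),
        # the published interval for this weight is inconsistent; a symmetric
        # 95% CI with the same spread is used instead
        beta("dw_acute_second_plus", "disability_weights.acute_second_plus",
             0.985, 0.981, 0.989),
        beta("dw_chronic_ihd", "disability_weights.chronic_ihd",
             0.08, 0.02, 0.24),
        beta("dw_chronic_stroke", "disability_weights.chronic_stroke",
             0.135, 0.01, 0.437),
        beta("dw_chronic_multi", "disability_weights.chronic_multi",
             0.242, 0.11, 0.437),
    ]

    return ConfigBundle(
        population=population,
        trajectory=TrajectoryConfig(),
        risk_model=risk_model,
        event_split=event_split,
        treatment_effect={
            "age_edges": [40.0, 50.0, 60.0, 70.0, 120.0],
            "sbp_edges": [140.0, 160.0, 180.0],
            "rr_ihd": treatment_effect_ihd,
            "rr_stroke": treatment_effect_stroke,
            "compliance_fraction": 0.503,
        },
        cascade=CascadeConfig(),
        ladder=ladder,
        transitions=transitions,
        costs=CostConfig(),
        disability_weights=DisabilityWeightsConfig(),
        lifetable=lifetable,
        economics=EconomicsConfig(),
        scenarios=scenarios,
        psa=psa,
    )


class FixtureSpec(BaseModel):
    """Specification of a flat-parameter miniature world."""

    name: str = "flat"
    cohort_size: int = Field(default=500, ge=0, description="per sex")
    seed: int = 0
    monthly_event_prob: float = Field(default=0.002, ge=0, le=1)
    p_mi_given_event: float = Field(default=0.5, ge=0, le=1)
    noncvd_death_monthly: float = Field(default=0.0, ge=0, le=1)
    acute_fatality: float = Field(default=0.0, ge=0, le=1)
    chronic_mortality_monthly: float = Field(default=0.0, ge=0, le=1)
    horizon_months: int = Field(default=240, ge=1)


@dataclass
class FlatWorld:
    """A flat-parameter world with its closed-form expectations."""

    spec: FixtureSpec
    config: ConfigBundle
    cohort: Cohort
    truths: Dict[str, Callable]
    transition_matrix: np.ndarray   # cohort Markov chain over the 7 states

    def expected_occupancy(self, n_cycles: int) -> np.ndarray:
        """(T, 7) expected state counts from matrix powers (the oracle)."""
        n = len(self.cohort)
        occ = np.zeros((n_cycles, self.transition_matrix.shape[0]))
        v = np.zeros(self.transition_matrix.shape[0])
        v[0] = n
        occ[0] = v
        for k in range(1, n_cycles):
            v = v @ self.transition_matrix
            occ[k] = v
        return occ


def make_flat_world(spec: FixtureSpec | None = None) -> FlatWorld:
    """Build a flat-parameter world admitting an exact cohort-Markov oracle.

    All probability tables are constant across age and sex; treatment
    coverage is zero so every individual follows the bare state machine.
    The accompanying transition matrix (order: WELL, ACUTE_MI, ACUTE_STROKE,
    POST_MI, POST_STROKE, POST_MULTI, DEAD) yields expected occupancies by
    matrix powers.
    """
    spec = spec or FixtureSpec()
    for name in ("monthly_event_prob", "noncvd_death_monthly", "acute_fatality",
                 "chronic_mortality_monthly"):
        v = getattr(spec, name)
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1]")

    base = make_default_config()
    flat = lambda v: AgeBandTable(edges=[0.0, 200.0], female=[v], male=[v])

    p10 = 1.0 - (1.0 - spec.monthly_event_prob) ** 120  # inverts the monthly conversion
    base.population.cohort_size = spec.cohort_size
    base.population.target_hypertension_prevalence = None
    base.risk_model = RiskModelConfig(
        baseline=flat(p10), coef_sbp=0.0, coef_bmi=0.0, coef_smoker=0.0)
    base.event_split = EventSplitConfig(p_mi=flat(spec.p_mi_given_event))
    annual_noncvd = 1.0 - (1.0 - spec.noncvd_death_monthly) ** 12
    base.transitions = TransitionConfig(
        mi_30d_fatality=flat(spec.acute_fatality),
        stroke_30d_fatality_female=spec.acute_fatality,
        stroke_30d_fatality_male=spec.acute_fatality,
        reinfarction_30d=0.0, stroke_after_mi_30d=0.0, repeat_stroke_30d=0.0,
        ihd_monthly_mortality=flat(spec.chronic_mortality_monthly),
        stroke_monthly_mortality=flat(spec.chronic_mortality_monthly),
        chronic_ihd_reinfarction=0.0,
        chronic_ihd_stroke=0.0,
        chronic_stroke_mi=0.0,
        chronic_stroke_stroke=0.0,
        chronic_recurrence_is_annual=False,
        non_cvd_death_annual=flat(annual_noncvd),
    )
    base.trajectory = TrajectoryConfig(
        sbp_band_edges=[0.0], slope_female=[0.0], slope_male=[0.0])
    base.scenarios = {
        "untreated": ScenarioSpec(label="untreated", coverage=0.0, adherence=0.0,
                                  protocol="IHCI_simplified",
                                  horizon_months=spec.horizon_months)}
    base.psa = []

    cohort = generate_cohort(base.population, seed=spec.seed)

    q = spec.noncvd_death_monthly
    p = spec.monthly_event_prob
    pm = spec.p_mi_given_event
    f = spec.acute_fatality
    r = spec.chronic_mortality_monthly
    # chronic recurrence is held at zero so event counts never exceed one and
    # the 7 states form an exact Markov chain (POST_MULTI stays empty)
    P = np.zeros((7, 7))
    # WELL: background death, first event split by type, else stay
    P[0, 6] = q
    P[0, 1] = (1 - q) * p * pm
    P[0, 2] = (1 - q) * p * (1 - pm)
    P[0, 0] = 1 - P[0, 6] - P[0, 1] - P[0, 2]
    # acute states: background death, 30-day fatality, else settle chronic
    for a, post in ((1, 3), (2, 4)):
        P[a, 6] = q + (1 - q) * f
        P[a, post] = 1 - P[a, 6]
    # chronic states: background + chronic death, else stay
    for c in (3, 4):
        P[c, 6] = q + (1 - q) * r
        P[c, c] = 1 - P[c, 6]
    P[5, 6] = q + (1 - q) * min(r * 1.5, 1.0)
    P[5, 5] = 1 - P[5, 6]
    P[6, 6] = 1.0

    n_total = 2 * spec.cohort_size
    truths = {
        # nobody has had an event, so WELL decays geometrically
        "well_occupancy": lambda k: n_total * ((1 - q) * (1 - p)) ** k,
        "alive_fraction": lambda k: (1 - q) ** k if p == 0 else None,
        "expected_first_events_total":
            lambda T: n_total * sum(
                ((1 - q) * (1 - p)) ** k * (1 - q) * p for k in range(T - 1)),
    }
    return FlatWorld(spec=spec, config=base, cohort=cohort, truths=truths,
                     transition_matrix=P)
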