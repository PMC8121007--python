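"""Costs, DALYs, ICERs, dominance classification and budget impact.

Costs accrue monthly from the simulation tallies in four components:

* antihypertensive treatment — ladder-step drug cost by sector, outpatient
  consultations while on treatment, and a one-time diagnostic work-up at
  initiation;
* acute CVD care — inpatient MI/stroke admissions at event cycles;
* chronic CVD care — secondary-prevention medication (dose tier by event
  history, price by sector) plus condition-specific outpatient follow-up;
* programmatic — the per-capita running cost of operating the intervention
  programme, applied to every cohort member every month in programme arms;
  it is flat in coverage and adherence and absent from the pre-intervention
  status quo.

Costs and DALYs are discounted at 3% per annum (monthly compounding of the
annual factor).  DALYs = YLD (disability weight × person-time, plus the
optional daily-medication disutility) + YLL (discounted residual life
expectancy at the age of death, attributed at the death cycle and counted in
full even past the simulation horizon).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional

import numpy as np
from scipy import optimize

from .config import (AgeBandTable, ConfigBundle, CostConfig,
                     DisabilityWeightsConfig, ScenarioSpec)
from .engine import SimulationResult

CostSchedule = CostConfig            # domain aliases
DisabilityWeights = DisabilityWeightsConfig

CLASS_COST_SAVING = "cost-saving"
CLASS_HIGHLY_CE = "highly cost-effective"
CLASS_CE = "cost-effective"
CLASS_NOT_CE = "not cost-effective"
CLASS_DOMINATED = "dominated"


@dataclass
class Thresholds:
    """GDP-anchored willingness-to-pay thresholds (US$ per DALY averted)."""

    gdp_per_capita: float = 2338.0

    @property
    def cost_effective(self) -> float:
        return self.gdp_per_capita

    @property
    def highly_cost_effective(self) -> float:
        return self.gdp_per_capita / 2.0


@dataclass
class CostStreams:
    """Undiscounted monthly cost streams (US$) by component."""

    antihypertensive: np.ndarray
    acute: np.ndarray
    chronic: np.ndarray
    programmatic: np.ndarray

    def __post_init__(self) -> None:
        for name in ("antihypertensive", "acute", "chronic", "programmatic"):
            if np.any(getattr(self, name) < 0):
                raise RuntimeError(f"negative cost stream: {name}")

    @property
    def total(self) -> np.ndarray:
        return (self.antihypertensive + self.acute + self.chronic
                + self.programmatic)

    def components(self) -> Dict[str, np.ndarray]:
        return {"antihypertensive": self.antihypertensive, "acute": self.acute,
                "chronic": self.chronic, "programmatic": self.programmatic}


def accrue_costs(result: SimulationResult, schedule: CostSchedule,
                 ladder, scenario: ScenarioSpec) -> CostStreams:
    """Build the monthly component cost streams from one arm's tallies."""
    T = result.horizon
    med_mult = schedule.medication_cost_multiplier

    drug_annual = np.zeros((len(ladder), 2))
    for s in ladder:
        drug_annual[s.step, 0] = s.annual_cost_public
        drug_annual[s.step, 1] = s.annual_cost_private
    anti = (result.treated_counts * drug_annual[None, :, :]).sum(axis=(1, 2)) \
        * med_mult / 12.0
    anti = anti + result.treated_total * schedule.opd_visit \
        * schedule.opd_visits_per_year / 12.0
    anti = anti + result.initiations * schedule.diagnostics_once

    acute = (result.events_mi * schedule.mi_inpatient
             + result.events_stroke * schedule.stroke_inpatient).astype(float)

    # chronic categories: single-event states on the low secondary-medication
    # tier, multi-event on the high tier; outpatient follow-up by condition
    sec = np.array([[schedule.secondary_med_annual_public[0],
                     schedule.secondary_med_annual_private[0]],
                    [schedule.secondary_med_annual_public[0],
                     schedule.secondary_med_annual_private[0]],
                    [schedule.secondary_med_annual_public[1],
                     schedule.secondary_med_annual_private[1]],
                    [schedule.secondary_med_annual_public[1],
                     schedule.secondary_med_annual_private[1]]])
    opd = np.array([schedule.ihd_opd_annual, schedule.stroke_opd_annual,
                    schedule.ihd_opd_annual, schedule.stroke_opd_annual])
    chronic = (result.chronic_counts * sec[None, :, :]).sum(axis=(1, 2)) / 12.0
    chronic = chronic + (result.chronic_counts.sum(axis=2) * opd[None, :]
                         ).sum(axis=1) / 12.0

    prog = np.zeros(T)
    if scenario.programmatic_cost_on:
        prog += result.n * schedule.programmatic_per_capita_annual \
            * schedule.programmatic_cost_multiplier / 12.0
    return CostStreams(antihypertensive=anti, acute=acute, chronic=chronic,
                       programmatic=prog)


def discount_factors(n_months: int, annual_rate: float) -> np.ndarray:
    k = np.arange(n_months)
    return (1.0 + annual_rate) ** (-k / 12.0)


def discount(stream: np.ndarray, annual_rate: float = 0.03) -> float:
    """Present value of a monthly stream: ``sum stream[k] * (1+r)^(-k/12)``."""
    if annual_rate < 0:
        raise ValueError("annual_rate must be >= 0")
    stream = np.asarray(stream, dtype=float)
    return float(stream @ discount_factors(len(stream), annual_rate))


@dataclass
class DALYResult:
    yld: float
    yll: float
    medication_disutility: float

    @property
    def total(self) -> float:
        return self.yld + self.yll + self.medication_disutility


def _discounted_life_years(L: np.ndarray, rate: float) -> np.ndarray:
    """Present value, at death, of L remaining life years (annuity form)."""
    if rate == 0:
        return L
    return (1.0 - (1.0 + rate) ** (-L)) / np.log(1.0 + rate)


def compute_dalys(result: SimulationResult, dw: DisabilityWeights,
                  life_table: AgeBandTable, annual_rate: float = 0.03,
                  medication_disutility_on: bool = False) -> DALYResult:
    """Discounted DALYs for one arm from its occupancy and death logs."""
    from .engine import HealthState
    T = result.horizon
    df = discount_factors(T, annual_rate)

    w = (result.acute_first_mi * dw.acute_mi
         + result.acute_first_stroke * dw.acute_stroke
         + result.acute_multi * dw.acute_second_plus
         + result.occupancy[:, int(HealthState.POST_MI)] * dw.chronic_ihd
         + result.occupancy[:, int(HealthState.POST_STROKE)] * dw.chronic_stroke
         + result.occupancy[:, int(HealthState.POST_MULTI)] * dw.chronic_multi)
    yld = float((w / 12.0) @ df)

    med = 0.0
    if medication_disutility_on:
        med = float((result.treated_total * dw.medication_daily / 12.0) @ df)

    yll = 0.0
    if len(result.death_log):
        ages = result.death_log["age"].to_numpy(float)
        sexes = result.death_log["sex"].to_numpy(int)
        cycles = result.death_log["cycle"].to_numpy(int)
        L = life_table.lookup(ages, sexes, clamp_top=True)
        Ld = _discounted_life_years(L, annual_rate)
        yll = float(np.sum(Ld * (1.0 + annual_rate) ** (-cycles / 12.0)))
    return DALYResult(yld=yld, yll=yll, medication_disutility=med)


@dataclass
class EconResult:
    """Discounted economic totals for one scenario arm."""

    label: str
    n: int
    horizon_months: int
    cost_components: Dict[str, float]     # discounted US$ over the cohort
    dalys: DALYResult
    events: int
    deaths: int
    cvd_deaths: int

    @property
    def total_cost(self) -> float:
        return float(sum(self.cost_components.values()))

    @property
    def total_dalys(self) -> float:
        return self.dalys.total

    def per_capita(self, value: float) -> float:
        return value / self.n if self.n else float("nan")

    @property
    def per_capita_cost(self) -> float:
        return self.per_capita(self.total_cost)


def summarize_arm(label: str, result: SimulationResult, streams: CostStreams,
                  dalys: DALYResult, annual_rate: float = 0.03) -> EconResult:
    comps = {k: discount(v, annual_rate) for k, v in streams.components().items()}
    return EconResult(label=label, n=result.n, horizon_months=result.horizon,
                      cost_components=comps, dalys=dalys,
                      events=result.total_events, deaths=result.total_deaths,
                      cvd_deaths=result.cvd_deaths)


@dataclass
class CEResult:
    """Incremental comparison of an intervention arm against a comparator."""

    intervention: str
    comparator: str
    n: int
    horizon_months: int
    delta_cost: float                     # intervention - comparator, US$
    delta_components: Dict[str, float]
    dalys_averted: float                  # comparator - intervention
    dalys_averted_pct: float
    events_averted_pct: float
    deaths_averted_pct: float
    icer: Optional[float]
    classification: str
    thresholds: Thresholds
    intervention_total_cost: float = 0.0

    @property
    def delta_cost_per_capita(self) -> float:
        return self.delta_cost / self.n

    @property
    def dalys_averted_per_capita(self) -> float:
        return self.dalys_averted / self.n


def compare(intervention: EconResult, comparator: EconResult,
            thresholds: Thresholds | None = None) -> CEResult:
    """ICER and dominance classification of two arms run under CRN.

    Cost-saving (dominant) arms — lower cost, DALYs averted — carry no ICER
    by convention; arms averting no DALYs at non-negative extra cost are
    dominated.
    """
    thresholds = thresholds or Thresholds()
    if intervention.n != comparator.n:
        raise ValueError("arms must share the cohort")
    dc = intervention.total_cost - comparator.total_cost
    da = comparator.total_dalys - intervention.total_dalys
    dcomp = {k: intervention.cost_components[k] - comparator.cost_components[k]
             for k in intervention.cost_components}
    ev_pct = (100.0 * (comparator.events - intervention.events) / comparator.events
              if comparator.events else 0.0)
    dth_pct = (100.0 * (comparator.deaths - intervention.deaths) / comparator.deaths
               if comparator.deaths else 0.0)
    da_pct = (100.0 * da / comparator.total_dalys
              if comparator.total_dalys else 0.0)

    icer: Optional[float] = None
    if da > 0 and dc < 0:
        cls = CLASS_COST_SAVING
    elif da <= 0:
        cls = CLASS_DOMINATED if dc >= 0 else CLASS_NOT_CE
    else:
        icer = dc / da
        if icer < thresholds.highly_cost_effective:
            cls = CLASS_HIGHLY_CE
        elif icer < thresholds.cost_effective:
            cls = CLASS_CE
        else:
            cls = CLASS_NOT_CE
    return CEResult(intervention=intervention.label, comparator=comparator.label,
                    n=intervention.n, horizon_months=intervention.horizon_months,
                    delta_cost=dc, delta_components=dcomp, dalys_averted=da,
                    dalys_averted_pct=da_pct, events_averted_pct=ev_pct,
                    deaths_averted_pct=dth_pct, icer=icer, classification=cls,
                    thresholds=thresholds,
                    intervention_total_cost=intervention.total_cost)


@dataclass
class BudgetImpact:
    """Cohort deltas scaled to a national population, per year of horizon."""

    annual_net_expenditure: float          # US$, negative = saving
    annual_components: Dict[str, float]
    national_population: float


def budget_impact(ce: CEResult, national_population_40_69: float) -> BudgetImpact:
    """Scale per-capita deltas to national annual net expenditure (linear)."""
    if ce.n <= 0:
        raise ValueError("cohort size must be > 0")
    if national_population_40_69 <= 0:
        raise ValueError("national population must be > 0")
    years = ce.horizon_months / 12.0
    scale = national_population_40_69 / ce.n / years
    return BudgetImpact(
        annual_net_expenditure=ce.delta_cost * scale,
        annual_components={k: v * scale for k, v in ce.delta_components.items()},
        national_population=national_population_40_69)


def threshold_analysis(ce: CEResult, thresholds: Thresholds | None = None,
                       threshold: float | None = None) -> float:
    """Largest uniform per-capita cost surcharge keeping the arm below threshold.

    Inflates the intervention arm's total cost by a multiplicative surcharge
    ``s`` until the ICER reaches the (default: highly-cost-effective)
    threshold; returns ``s`` as a percentage.  Returns 0 if the base
    comparison is already at or beyond the threshold, and ``inf`` for an
    unbounded threshold.
    """
    thresholds = thresholds or ce.thresholds
    thr = thresholds.highly_cost_effective if threshold is None else threshold
    if np.isinf(thr):
        return float("inf")
    if ce.dalys_averted <= 0:
        return 0.0
    base = ce.intervention_total_cost

    def icer_gap(s: float) -> float:
        return (ce.delta_cost + s * base) / ce.dalys_averted - thr

    if icer_gap(0.0) >= 0:
        return 0.0
    hi = 1.0
    while icer_gap(hi) < 0 and hi < 1e6:
        hi *= 2.0
    s = optimize.brentq(icer_gap, 0.0, hi, xtol=1e-12)
    return 100.0 * s


def run_arm_economics(label: str, result: SimulationResult, bundle: ConfigBundle,
                      scenario: ScenarioSpec) -> EconResult:
    """Convenience: streams + DALYs + discounting for one simulated arm."""
    streams = accrue_costs(result, bundle.costs, bundle.ladder, scenario)
    dalys = compute_dalys(result, bundle.disability_weights, bundle.lifetable,
                          bundle.economics.discount_rate,
                          scenario.medication_disutility_on)
    return summarize_arm(label, result, streams, dalys,
                         bundle.economics.discount_rate)
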