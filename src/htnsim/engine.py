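"""Monthly discrete-time microsimulation over the CVD health-state machine.

States: WELL (no past CVD event) → acute MI/stroke (a single 30-day cycle
housing the acute-fatality and early-recurrence probabilities) → chronic
post-MI / post-stroke states, with a POST_MULTI bookkeeping state for
individuals with two or more lifetime events (they face 1.5× fatality and
their own disability weight).  DEAD is absorbing.

Within-cycle event order: (1) non-CVD death, (2) CVD death — 30-day fatality
in acute states, chronic cause-specific mortality otherwise, (3) first or
recurrent CVD event, (4) risk-factor update (age monthly, SBP annually).

Antihypertensive treatment multiplies the monthly first-event probability of
individuals in WELL by the effective relative risk for their adherence
class; published recurrence probabilities are used untouched.  All draws go
through the CRN streams in :mod:`htnsim.rng`, so arms sharing a master seed
are event-by-event comparable.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import numpy as np
import pandas as pd

from . import rng as crn
from .cascade import CascadeState, CascadeStates
from .config import (ConfigBundle, ConfigError, ScenarioSpec, TrajectoryConfig,
                     TransitionConfig)
from .population import Cohort
from .risk import (ADHERENCE_FULL, ADHERENCE_NONE, ADHERENCE_PARTIAL,
                   EventTypeSplit, RiskModel, TreatmentEffect,
                   effective_rr_arrays, risk_to_monthly_prob)

PERSISTENCE_CUTOFF_MONTHS = 12  # non-persistent individuals drop out after year 1


class HealthState(IntEnum):
    WELL = 0
    ACUTE_MI = 1
    ACUTE_STROKE = 2
    POST_MI = 3
    POST_STROKE = 4
    POST_MULTI = 5
    DEAD = 6


N_STATES = len(HealthState)
EVENT_NONE, EVENT_MI, EVENT_STROKE = 0, 1, 2

# chronic cost/disability categories: (post-MI, post-stroke, multi after MI,
# multi after stroke)
CHRONIC_CATEGORIES = ("post_mi", "post_stroke", "multi_mi", "multi_stroke")


@dataclass
class TransitionParameters:
    """Compiled transition-probability tables."""

    config: TransitionConfig

    def __post_init__(self) -> None:
        cfg = self.config
        if cfg.chronic_recurrence_is_annual:
            conv = lambda p: 1.0 - (1.0 - p) ** (1.0 / 12.0)
        else:
            conv = lambda p: p
        # monthly chronic recurrence probabilities, rows indexed by prior
        # event type: [P(MI), P(stroke)]
        self.q_chronic = {
            EVENT_MI: (conv(cfg.chronic_ihd_reinfarction), conv(cfg.chronic_ihd_stroke)),
            EVENT_STROKE: (conv(cfg.chronic_stroke_mi), conv(cfg.chronic_stroke_stroke)),
        }

    def noncvd_monthly(self, age, sex) -> np.ndarray:
        annual = self.config.non_cvd_death_annual.lookup(age, sex, clamp_top=True)
        return 1.0 - (1.0 - annual) ** (1.0 / 12.0)

    def mi_fatality(self, age, sex) -> np.ndarray:
        return self.config.mi_30d_fatality.lookup(age, sex, clamp_top=True)

    def stroke_fatality(self, sex) -> np.ndarray:
        vals = np.asarray([self.config.stroke_30d_fatality_female,
                           self.config.stroke_30d_fatality_male])
        return vals[np.asarray(sex, dtype=int)]

    def chronic_mortality(self, last_type, age, sex) -> np.ndarray:
        ihd = self.config.ihd_monthly_mortality.lookup(age, sex, clamp_top=True)
        stk = self.config.stroke_monthly_mortality.lookup(age, sex, clamp_top=True)
        return np.where(np.asarray(last_type) == EVENT_MI, ihd, stk)


@dataclass
class ModelParams:
    """Everything :func:`run_cohort` needs beyond the cohort and cascade."""

    transitions: TransitionParameters
    risk_model: RiskModel
    event_split: EventTypeSplit
    treatment_effect: TreatmentEffect
    trajectory: TrajectoryConfig

    @classmethod
    def from_config(cls, bundle: ConfigBundle) -> "ModelParams":
        return cls(
            transitions=TransitionParameters(bundle.transitions),
            risk_model=RiskModel(bundle.risk_model),
            event_split=EventTypeSplit(bundle.event_split),
            treatment_effect=TreatmentEffect(bundle.treatment_effect),
            trajectory=bundle.trajectory,
        )


@dataclass
class PersonState:
    """Scalar health state plus event history for one individual."""

    state: HealthState = HealthState.WELL
    event_count: int = 0
    last_event_type: int = EVENT_NONE


@dataclass
class SimulationResult:
    """Per-cycle tallies and logs from one cohort run."""

    horizon: int
    n: int
    occupancy: np.ndarray            # (T, 7) state counts per cycle
    acute_first_mi: np.ndarray       # (T,) person-months in first acute MI
    acute_first_stroke: np.ndarray
    acute_multi: np.ndarray          # (T,) acute months of 2nd+ events
    events_mi: np.ndarray            # (T,) new MI events at cycle
    events_stroke: np.ndarray
    treated_counts: np.ndarray       # (T, n_steps, 2 sectors) on-treatment counts
    treated_total: np.ndarray        # (T,) persons on antihypertensives
    chronic_counts: np.ndarray       # (T, 4 categories, 2 sectors)
    initiations: np.ndarray          # (T,) diagnostics-triggering initiations
    event_log: pd.DataFrame          # cycle, individual, type, event_number, first
    death_log: pd.DataFrame          # cycle, individual, cause, age, sex

    @property
    def total_events(self) -> int:
        return int(self.events_mi.sum() + self.events_stroke.sum())

    @property
    def total_deaths(self) -> int:
        return len(self.death_log)

    @property
    def cvd_deaths(self) -> int:
        return int((self.death_log["cause"] == "cvd").sum())

    def occupancy_frame(self) -> pd.DataFrame:
        """Tidy per-cycle occupancy (cycle, state, count)."""
        frames = []
        for s in HealthState:
            frames.append(pd.DataFrame({
                "cycle": np.arange(self.horizon), "state": s.name,
                "count": self.occupancy[:, int(s)]}))
        return pd.concat(frames, ignore_index=True)


def _transition_kernel(state, event_count, last_type, age, sbp, baseline_sbp,
                       bmi, smoker, sex, adherence_class, params: ModelParams,
                       u0, u1, u2, u3):
    """One cycle of transitions for arrays of individuals.

    Returns (new_state, new_count, new_last, died_noncvd, died_cvd,
    new_mi, new_stroke) boolean masks over the input arrays.
    """
    tp = params.transitions
    alive = state != HealthState.DEAD

    # (1) background (non-CVD) mortality
    died_noncvd = alive & (u0 < tp.noncvd_monthly(age, sex))
    still = alive & ~died_noncvd

    # (2) CVD mortality: 30-day fatality in acute states, chronic otherwise;
    #     1.5x relative fatality for individuals with 2+ lifetime events
    multi = event_count >= 2
    rr_fat = np.where(multi, tp.config.rr_multi_event_fatality, 1.0)
    p_fatal = np.zeros_like(u1)
    m_ami = state == HealthState.ACUTE_MI
    m_ast = state == HealthState.ACUTE_STROKE
    m_chronic = (state == HealthState.POST_MI) | (state == HealthState.POST_STROKE) \
        | (state == HealthState.POST_MULTI)
    p_fatal[m_ami] = tp.mi_fatality(age[m_ami], sex[m_ami])
    p_fatal[m_ast] = tp.stroke_fatality(sex[m_ast])
    p_fatal[m_chronic] = tp.chronic_mortality(
        last_type[m_chronic], age[m_chronic], sex[m_chronic])
    p_fatal = np.minimum(p_fatal * rr_fat, 1.0)
    died_cvd = still & (u1 < p_fatal) & (m_ami | m_ast | m_chronic)
    survivors = still & ~died_cvd

    # (3) first or recurrent CVD events
    p_mi = np.zeros_like(u2)
    p_st = np.zeros_like(u2)

    well = survivors & (state == HealthState.WELL)
    if np.any(well):
        p10 = params.risk_model.ten_year_risk(
            age[well], sex[well], sbp[well], bmi[well], smoker[well])
        pm = risk_to_monthly_prob(p10)
        split = params.event_split.p_mi(age[well], sex[well])
        rr_i, rr_s = effective_rr_arrays(
            params.treatment_effect, age[well], baseline_sbp[well],
            adherence_class[well])
        p_mi[well] = pm * split * rr_i
        p_st[well] = pm * (1.0 - split) * rr_s

    a_mi = survivors & m_ami
    p_mi[a_mi] = tp.config.reinfarction_30d
    p_st[a_mi] = tp.config.stroke_after_mi_30d
    a_st = survivors & m_ast
    p_st[a_st] = tp.config.repeat_stroke_30d

    for st, key in ((HealthState.POST_MI, EVENT_MI),
                    (HealthState.POST_STROKE, EVENT_STROKE)):
        m = survivors & (state == st)
        p_mi[m], p_st[m] = tp.q_chronic[key]
    m_multi = survivors & (state == HealthState.POST_MULTI)
    if np.any(m_multi):
        q_mi = np.where(last_type[m_multi] == EVENT_MI,
                        tp.q_chronic[EVENT_MI][0], tp.q_chronic[EVENT_STROKE][0])
        q_st = np.where(last_type[m_multi] == EVENT_MI,
                        tp.q_chronic[EVENT_MI][1], tp.q_chronic[EVENT_STROKE][1])
        p_mi[m_multi], p_st[m_multi] = q_mi, q_st

    p_tot = p_mi + p_st
    has_event = survivors & (u2 < p_tot)
    # type split without dividing by a possibly-zero total
    is_mi = has_event & (u3 * p_tot < p_mi)
    new_mi = has_event & is_mi
    new_stroke = has_event & ~is_mi

    # -- resolve new states --------------------------------------------------
    new_state = state.copy()
    new_count = event_count.copy()
    new_last = last_type.copy()

    new_state[died_noncvd | died_cvd] = HealthState.DEAD

    # acute survivors without an early recurrence settle into chronic states
    settle_mi = a_mi & ~has_event
    settle_st = a_st & ~has_event
    new_state[settle_mi] = np.where(event_count[settle_mi] >= 2,
                                    HealthState.POST_MULTI, HealthState.POST_MI)
    new_state[settle_st] = np.where(event_count[settle_st] >= 2,
                                    HealthState.POST_MULTI, HealthState.POST_STROKE)

    new_state[new_mi] = HealthState.ACUTE_MI
    new_state[new_stroke] = HealthState.ACUTE_STROKE
    new_count[has_event] += 1
    new_last[new_mi] = EVENT_MI
    new_last[new_stroke] = EVENT_STROKE

    return new_state, new_count, new_last, died_noncvd, died_cvd, new_mi, new_stroke


class _Kernel:
    """Binds the per-run constant arrays the transition kernel needs."""

    def __init__(self, params: ModelParams, sex, bmi, smoker, baseline_sbp):
        self.params = params
        self.sex = sex
        self.bmi = bmi
        self.smoker = smoker
        self.baseline_sbp = baseline_sbp

    def step(self, state, event_count, last_type, age, sbp, adherence_class,
             u0, u1, u2, u3):
        return _transition_kernel(
            state, event_count, last_type, age, sbp, self.baseline_sbp,
            self.bmi, self.smoker, self.sex, adherence_class, self.params,
            u0, u1, u2, u3)


def step_individual(person: PersonState, profile, cascade_state: CascadeState,
                    params: ModelParams, rng: np.random.Generator,
                    cycle: int) -> tuple[PersonState, list[str]]:
    """Advance one individual by one cycle; returns the new state and events.

    A thin scalar wrapper over the vectorised kernel, drawing the cycle's
    four uniforms from ``rng``.
    """
    if person.state == HealthState.DEAD:
        return PersonState(HealthState.DEAD, person.event_count,
                           person.last_event_type), []
    from .config import MALE
    sexc = np.array([MALE if profile.sex == "male" else 0])
    cls = {"none": ADHERENCE_NONE, "partial": ADHERENCE_PARTIAL,
           "full": ADHERENCE_FULL}[cascade_state.adherence_class]
    on = cascade_state.initiated and (cascade_state.persistent
                                      or cycle < PERSISTENCE_CUTOFF_MONTHS)
    if on and cls == ADHERENCE_NONE:
        cls = ADHERENCE_PARTIAL   # non-persistent, still inside year 1
    if not on:
        cls = ADHERENCE_NONE
    kern = _Kernel(params, sexc, np.array([profile.bmi]),
                   np.array([float(profile.smoker)]),
                   np.array([profile.baseline_sbp]))
    u = rng.random(4)
    st, cnt, last, dn, dc, mi, stk = kern.step(
        np.array([int(person.state)]), np.array([person.event_count]),
        np.array([person.last_event_type]), np.array([profile.age]),
        np.array([profile.sbp]), np.array([cls], dtype=np.int8),
        *[np.array([x]) for x in u])
    events = []
    if dn[0]:
        events.append("non_cvd_death")
    if dc[0]:
        events.append("cvd_death")
    if mi[0]:
        events.append("MI")
    if stk[0]:
        events.append("stroke")
    return PersonState(HealthState(int(st[0])), int(cnt[0]), int(last[0])), events


def run_cohort(cohort: Cohort, cascade_states: CascadeStates,
               scenario: ScenarioSpec, params: ModelParams,
               seed: int, n_ladder_steps: int = 4) -> SimulationResult:
    """Run the monthly microsimulation for one scenario arm.

    Deterministic given ``seed``; conservation of cohort size over states
    holds at every cycle.  Month 0 is the enrolment month: everyone is WELL,
    treatment (and its costs) starts, no transitions occur.
    """
    T = scenario.horizon_months
    if T < 1:
        raise ConfigError("horizon_months must be >= 1")
    n = len(cohort)

    occupancy = np.zeros((T, N_STATES), dtype=np.int64)
    acute_first_mi = np.zeros(T, dtype=np.int64)
    acute_first_stroke = np.zeros(T, dtype=np.int64)
    acute_multi = np.zeros(T, dtype=np.int64)
    events_mi = np.zeros(T, dtype=np.int64)
    events_stroke = np.zeros(T, dtype=np.int64)
    treated_counts = np.zeros((T, n_ladder_steps, 2), dtype=np.int64)
    treated_total = np.zeros(T, dtype=np.int64)
    chronic_counts = np.zeros((T, len(CHRONIC_CATEGORIES), 2), dtype=np.int64)
    initiations = np.zeros(T, dtype=np.int64)
    ev_rows: list[tuple] = []
    death_rows: list[tuple] = []

    if n == 0:
        return SimulationResult(
            horizon=T, n=0, occupancy=occupancy, acute_first_mi=acute_first_mi,
            acute_first_stroke=acute_first_stroke, acute_multi=acute_multi,
            events_mi=events_mi, events_stroke=events_stroke,
            treated_counts=treated_counts, treated_total=treated_total,
            chronic_counts=chronic_counts, initiations=initiations,
            event_log=_event_frame(ev_rows), death_log=_death_frame(death_rows))

    state = np.zeros(n, dtype=np.int64)
    event_count = np.zeros(n, dtype=np.int64)
    last_type = np.zeros(n, dtype=np.int64)
    age = cohort.age.astype(float).copy()
    sbp = cohort.sbp.astype(float).copy()
    sex = cohort.sex.astype(int)

    cs = cascade_states
    kern = _Kernel(params, sex, cohort.bmi.astype(float),
                   cohort.smoker.astype(float), cohort.baseline_sbp.astype(float))

    initiations[0] = int(cs.initiated.sum())

    def adherence_now(cycle: int) -> np.ndarray:
        on = cs.initiated & (cs.persistent | (cycle < PERSISTENCE_CUTOFF_MONTHS))
        cls = np.full(n, ADHERENCE_NONE, dtype=np.int8)
        cls[on] = ADHERENCE_PARTIAL
        cls[on & cs.compliant] = ADHERENCE_FULL
        return cls

    def tally(cycle: int, alive_at_start: np.ndarray, cls: np.ndarray,
              new_mi=None, new_stroke=None) -> None:
        occupancy[cycle] = np.bincount(state, minlength=N_STATES)
        if new_mi is not None:
            events_mi[cycle] = int(new_mi.sum())
            events_stroke[cycle] = int(new_stroke.sum())
        in_ami = state == HealthState.ACUTE_MI
        in_ast = state == HealthState.ACUTE_STROKE
        multi = event_count >= 2
        acute_first_mi[cycle] = int((in_ami & ~multi).sum())
        acute_first_stroke[cycle] = int((in_ast & ~multi).sum())
        acute_multi[cycle] = int(((in_ami | in_ast) & multi).sum())
        on = (cls != ADHERENCE_NONE) & alive_at_start
        treated_total[cycle] = int(on.sum())
        if np.any(on):
            flat = cs.protocol_step[on].astype(int) * 2 + cs.sector[on].astype(int)
            counts = np.bincount(flat, minlength=n_ladder_steps * 2)
            treated_counts[cycle] = counts.reshape(n_ladder_steps, 2)
        cat = np.full(n, -1, dtype=int)
        cat[state == HealthState.POST_MI] = 0
        cat[state == HealthState.POST_STROKE] = 1
        m = state == HealthState.POST_MULTI
        cat[m & (last_type == EVENT_MI)] = 2
        cat[m & (last_type == EVENT_STROKE)] = 3
        has = cat >= 0
        if np.any(has):
            flat = cat[has] * 2 + cs.sector[has].astype(int)
            counts = np.bincount(flat, minlength=len(CHRONIC_CATEGORIES) * 2)
            chronic_counts[cycle] = counts.reshape(len(CHRONIC_CATEGORIES), 2)

    # month 0: enrolment, everyone WELL
    tally(0, np.ones(n, dtype=bool), adherence_now(0))

    for cycle in range(1, T):
        alive_at_start = state != HealthState.DEAD
        cls = adherence_now(cycle)
        cls[~alive_at_start] = ADHERENCE_NONE
        u0 = crn.uniform_array(seed, cycle, crn.SLOT_NONCVD_DEATH, n)
        u1 = crn.uniform_array(seed, cycle, crn.SLOT_CVD_FATALITY, n)
        u2 = crn.uniform_array(seed, cycle, crn.SLOT_EVENT, n)
        u3 = crn.uniform_array(seed, cycle, crn.SLOT_EVENT_TYPE, n)
        state, event_count, last_type, dn, dc, new_mi, new_stroke = kern.step(
            state, event_count, last_type, age, sbp, cls, u0, u1, u2, u3)

        for mask, cause in ((dn, "non_cvd"), (dc, "cvd")):
            for i in np.flatnonzero(mask):
                death_rows.append((cycle, int(cohort.ids[i]), cause,
                                   float(age[i]), int(sex[i])))
        for mask, etype in ((new_mi, "MI"), (new_stroke, "stroke")):
            for i in np.flatnonzero(mask):
                ev_rows.append((cycle, int(cohort.ids[i]), etype,
                                int(event_count[i])))

        tally(cycle, alive_at_start, cls, new_mi, new_stroke)

        # (4) risk-factor update for survivors
        alive = state != HealthState.DEAD
        age[alive] += 1.0 / 12.0
        if cycle % 12 == 0:
            slope = params.trajectory.slope(sex, cohort.baseline_sbp)
            sbp[alive] += slope[alive]

    return SimulationResult(
        horizon=T, n=n, occupancy=occupancy, acute_first_mi=acute_first_mi,
        acute_first_stroke=acute_first_stroke, acute_multi=acute_multi,
        events_mi=events_mi, events_stroke=events_stroke,
        treated_counts=treated_counts, treated_total=treated_total,
        chronic_counts=chronic_counts, initiations=initiations,
        event_log=_event_frame(ev_rows), death_log=_death_frame(death_rows))


def _event_frame(rows) -> pd.DataFrame:
    df = pd.DataFrame(rows, columns=["cycle", "individual", "type", "event_number"])
    df["first"] = df["event_number"] == 1
    return df


def _death_frame(rows) -> pd.DataFrame:
    return pd.DataFrame(rows, columns=["cycle", "individual", "cause", "age", "sex"])
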