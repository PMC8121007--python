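"""Scenario grids, probabilistic sensitivity analysis and one-way sensitivity.

All experiment drivers pair arms with common random numbers: the cohort and
every in-simulation draw derive from one master seed, so scenario contrasts
are event-by-event paired.  The PSA re-samples uncertain parameters (those
shipped with 95% CIs, beta-sampled by moment matching) per draw and reruns
both arms under a per-draw CRN seed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .cascade import apply_cascade
from .config import ConfigBundle, ParameterDistribution, ScenarioSpec
from .economics import (CEResult, EconResult, Thresholds, compare,
                        run_arm_economics)
from .engine import ModelParams, SimulationResult, run_cohort
from .population import generate_cohort

log = logging.getLogger(__name__)

ONE_WAY_SCENARIOS = (
    "double_medication_cost",
    "quadruple_programmatic_cost",
    "baseline_risk_minus_20pct",
    "npcdcs_protocol",
    "medication_disutility",
    "horizon_10y",
    "horizon_40y",
    "private_sector_80pct",
)


@dataclass
class ArmRun:
    """One simulated scenario arm with its economic summary."""

    scenario: ScenarioSpec
    sim: SimulationResult
    econ: EconResult


def simulate_arm(bundle: ConfigBundle, scenario: ScenarioSpec, seed: int,
                 cohort=None) -> ArmRun:
    """Generate (or reuse) the cohort, run the cascade and engine, summarise.

    Passing the same ``seed`` (and cohort) for two scenarios yields CRN-paired
    arms.
    """
    if cohort is None:
        cohort = generate_cohort(bundle.population, seed=seed)
    params = ModelParams.from_config(bundle)
    baseline_risk = params.risk_model.ten_year_risk(
        cohort.baseline_age, cohort.sex, cohort.baseline_sbp, cohort.bmi,
        cohort.smoker)
    cascade_states = apply_cascade(cohort, scenario, bundle.cascade,
                                   baseline_risk, seed, bundle.ladder)
    sim = run_cohort(cohort, cascade_states, scenario, params, seed,
                     n_ladder_steps=len(bundle.ladder))
    econ = run_arm_economics(scenario.label or "arm", sim, bundle, scenario)
    return ArmRun(scenario=scenario, sim=sim, econ=econ)


def compare_scenarios(bundle: ConfigBundle, intervention: ScenarioSpec,
                      comparator: ScenarioSpec, seed: int) -> tuple[CEResult, ArmRun, ArmRun]:
    """CRN-paired comparison of two scenario arms under one config."""
    cohort = generate_cohort(bundle.population, seed=seed)
    arm_i = simulate_arm(bundle, intervention, seed, cohort=cohort)
    arm_c = simulate_arm(bundle, comparator, seed, cohort=cohort)
    thresholds = Thresholds(gdp_per_capita=bundle.economics.gdp_per_capita)
    ce = compare(arm_i.econ, arm_c.econ, thresholds)
    return ce, arm_i, arm_c


# ---------------------------------------------------------------------------
# parameter sampling
# ---------------------------------------------------------------------------

def _beta_moments(point: float, lower: float, upper: float) -> Optional[tuple[float, float]]:
    sd = (upper - lower) / (2.0 * 1.96)
    var = sd * sd
    if var <= 0 or point <= 0 or point >= 1 or var >= point * (1.0 - point):
        return None
    k = point * (1.0 - point) / var - 1.0
    return point * k, (1.0 - point) * k


def sample_value(dist: ParameterDistribution, rng: np.random.Generator) -> float:
    """One draw from a parameter's uncertainty distribution.

    Beta parameters come from moment matching (mean = point estimate,
    sd = CI width / 3.92); infeasible moments fall back to the point with a
    warning.  Gamma uses the same moments; 'fixed' always returns the point.
    """
    if dist.family == "fixed":
        return dist.point
    sd = (dist.upper95 - dist.lower95) / (2.0 * 1.96)
    if sd == 0:
        return dist.point
    if dist.family == "beta":
        ab = _beta_moments(dist.point, dist.lower95, dist.upper95)
        if ab is None:
            warnings.warn(f"{dist.name}: infeasible beta moments, using point")
            return dist.point
        return float(rng.beta(*ab))
    shape = (dist.point / sd) ** 2
    scale = sd * sd / dist.point
    return float(rng.gamma(shape, scale))


def _set_dotted(bundle: ConfigBundle, path: str, value: float) -> None:
    obj = bundle
    parts = path.split(".")
    for p in parts[:-1]:
        obj = getattr(obj, p)
    if not hasattr(obj, parts[-1]):
        raise AttributeError(f"unknown parameter target {path!r}")
    setattr(obj, parts[-1], value)


def sample_parameter_set(distributions: Sequence[ParameterDistribution],
                         rng: np.random.Generator,
                         base: ConfigBundle) -> ConfigBundle:
    """An independently-sampled copy of the config bundle for one PSA draw."""
    draw = base.model_copy(deep=True)
    for dist in distributions:
        _set_dotted(draw, dist.target, sample_value(dist, rng))
    return draw


# ---------------------------------------------------------------------------
# drivers
# ---------------------------------------------------------------------------

def _ce_row(coverage, adherence, ce: CEResult) -> dict:
    return {
        "coverage": coverage, "adherence": adherence,
        "delta_cost": ce.delta_cost,
        "delta_cost_per_capita": ce.delta_cost_per_capita,
        "dalys_averted": ce.dalys_averted,
        "dalys_averted_pct": ce.dalys_averted_pct,
        "events_averted_pct": ce.events_averted_pct,
        "icer": np.nan if ce.icer is None else ce.icer,
        "classification": ce.classification,
    }


def run_scenario_grid(bundle: ConfigBundle, coverages: Iterable[float],
                      adherences: Iterable[float], seed: int,
                      status_quo: ScenarioSpec | None = None,
                      protocol: str = "IHCI_simplified") -> pd.DataFrame:
    """One CE comparison per (coverage, adherence) cell against the status quo.

    Intervention arms use the simplified (SBP >= 140) protocol; the status-quo
    comparator runs once with the NPCDCS guideline.  All arms share the master
    seed (CRN).
    """
    coverages = list(coverages)
    adherences = list(adherences)
    if not coverages or not adherences:
        return pd.DataFrame(columns=list(_ce_row(0, 0, _null_ce()).keys()))
    sq = status_quo or bundle.scenarios.get("status_quo") or ScenarioSpec(
        label="status_quo", coverage=0.17, adherence=0.30, protocol="NPCDCS")
    cohort = generate_cohort(bundle.population, seed=seed)
    arm_sq = simulate_arm(bundle, sq, seed, cohort=cohort)
    thresholds = Thresholds(gdp_per_capita=bundle.economics.gdp_per_capita)
    rows = []
    for cov in coverages:
        for adh in adherences:
            sc = ScenarioSpec(label=f"cov{cov:g}_adh{adh:g}", coverage=cov,
                              adherence=adh, protocol=protocol,
                              horizon_months=sq.horizon_months)
            arm = simulate_arm(bundle, sc, seed, cohort=cohort)
            ce = compare(arm.econ, arm_sq.econ, thresholds)
            rows.append(_ce_row(cov, adh, ce))
    return pd.DataFrame(rows)


def _null_ce() -> CEResult:
    return CEResult(intervention="", comparator="", n=1, horizon_months=1,
                    delta_cost=0.0, delta_components={}, dalys_averted=0.0,
                    dalys_averted_pct=0.0, events_averted_pct=0.0,
                    deaths_averted_pct=0.0, icer=None, classification="",
                    thresholds=Thresholds())


@dataclass
class PSAResult:
    """Per-draw incremental outcomes and their summary."""

    draws: pd.DataFrame                  # draw, delta_cost, dalys_averted
    probability_cost_saving: float
    quantiles: Dict[str, Dict[str, float]]
    master_seed: int

    @property
    def n_draws(self) -> int:
        return len(self.draws)


def _child_seed(master: int, draw: int) -> int:
    return int(np.random.SeedSequence((master, draw)).generate_state(1)[0] % (2**31))


def run_psa(bundle: ConfigBundle, scenario: ScenarioSpec, seed: int,
            n_draws: int = 1000,
            status_quo: ScenarioSpec | None = None) -> PSAResult:
    """Probabilistic sensitivity analysis.

    Each draw jointly re-samples the CI-carrying parameters, then reruns the
    intervention and status-quo arms under a per-draw CRN seed; the
    probability of cost saving is the fraction of draws with lower cost and
    DALYs averted.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    sq = status_quo or bundle.scenarios.get("status_quo") or ScenarioSpec(
        label="status_quo", coverage=0.17, adherence=0.30, protocol="NPCDCS")
    rows = []
    for d in range(n_draws):
        rng = np.random.default_rng(np.random.SeedSequence((seed, d, 999)))
        cfg = sample_parameter_set(bundle.psa, rng, bundle)
        sim_seed = _child_seed(seed, d)
        ce, _, _ = compare_scenarios(cfg, scenario, sq, sim_seed)
        rows.append({"draw": d, "delta_cost": ce.delta_cost,
                     "delta_cost_per_capita": ce.delta_cost_per_capita,
                     "dalys_averted": ce.dalys_averted,
                     "dalys_averted_pct": ce.dalys_averted_pct})
    df = pd.DataFrame(rows)
    saving = float(np.mean((df["delta_cost"] < 0) & (df["dalys_averted"] > 0)))
    qs = {}
    for col in ("delta_cost", "dalys_averted"):
        q = df[col].quantile([0.025, 0.5, 0.975])
        qs[col] = {"q025": float(q.iloc[0]), "median": float(q.iloc[1]),
                   "q975": float(q.iloc[2])}
    return PSAResult(draws=df, probability_cost_saving=saving, quantiles=qs,
                     master_seed=seed)


def _one_way_transform(name: str, bundle: ConfigBundle,
                       scenario: ScenarioSpec, status_quo: ScenarioSpec):
    """Apply one named sensitivity transform; returns (bundle, scenario, sq)."""
    b = bundle.model_copy(deep=True)
    sc = scenario.model_copy()
    sq = status_quo.model_copy()
    if name == "double_medication_cost":
        b.costs.medication_cost_multiplier *= 2.0
    elif name == "quadruple_programmatic_cost":
        b.costs.programmatic_cost_multiplier *= 4.0
    elif name == "baseline_risk_minus_20pct":
        b.risk_model.risk_multiplier *= 0.8
    elif name == "npcdcs_protocol":
        sc.protocol = "NPCDCS"
    elif name == "medication_disutility":
        sc.medication_disutility_on = True
        sq.medication_disutility_on = True
    elif name == "horizon_10y":
        sc.horizon_months = 120
        sq.horizon_months = 120
    elif name == "horizon_40y":
        sc.horizon_months = 480
        sq.horizon_months = 480
    elif name == "private_sector_80pct":
        sc.public_fraction = 0.2
        sq.public_fraction = 0.2
    elif name != "base":
        raise ValueError(f"unknown one-way scenario {name!r}")
    sc.label = f"{scenario.label}+{name}" if name != "base" else scenario.label
    return b, sc, sq


def run_one_way_suite(bundle: ConfigBundle, seed: int,
                      scenario: ScenarioSpec | None = None,
                      status_quo: ScenarioSpec | None = None,
                      names: Sequence[str] = ONE_WAY_SCENARIOS) -> pd.DataFrame:
    """Run the named one-way sensitivity transforms plus the base comparison.

    The ICER is suppressed (NaN) whenever the transform averts no DALYs —
    e.g. when the daily-medication disutility outweighs health gains.
    """
    scenario = scenario or bundle.scenarios.get("seventy") or ScenarioSpec(
        label="seventy", coverage=0.70, adherence=0.70)
    sq = status_quo or bundle.scenarios.get("status_quo") or ScenarioSpec(
        label="status_quo", coverage=0.17, adherence=0.30, protocol="NPCDCS")
    rows = []
    for name in ["base", *names]:
        b, sc, sq_t = _one_way_transform(name, bundle, scenario, sq)
        ce, _, _ = compare_scenarios(b, sc, sq_t, seed)
        rows.append({
            "scenario": name, "delta_cost": ce.delta_cost,
            "delta_cost_per_capita": ce.delta_cost_per_capita,
            "dalys_averted": ce.dalys_averted,
            "dalys_averted_pct": ce.dalys_averted_pct,
            "events_averted_pct": ce.events_averted_pct,
            "icer": np.nan if ce.icer is None else ce.icer,
            "classification": ce.classification,
        })
    return pd.DataFrame(rows)
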