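"""Configuration schema for the hypertension-control microsimulation.

All model inputs — population distributions, the cardiovascular risk surface,
treatment-effect tables, the care cascade, transition probabilities, unit
costs, disability weights, the lifetable and scenario definitions — live in a
single validated :class:`ConfigBundle`.  Bundles round-trip losslessly through
YAML, and a canonical SHA-256 hash identifies a bundle for run manifests.

Costs are handled internally in US dollars; a bundle whose ``costs.currency``
is ``"INR"`` is converted once at validation-exit using the configured
exchange rate (default ₹70 = $1).
"""

from __future__ import annotations

import hashlib
from typing import Dict, List, Literal, Optional, Tuple

import numpy as np
import yaml
from pydantic import BaseModel, Field, model_validator

Sex = Literal["female", "male"]
Protocol = Literal["IHCI_simplified", "NPCDCS"]

#: integer sex codes used throughout the array layer
FEMALE, MALE = 0, 1


class ConfigError(ValueError):
    """A configuration value violates a model invariant."""


class AgeBandTable(BaseModel):
    """A per-sex quantity tabulated over contiguous age bands.

    ``edges`` are band boundaries ``[e0, e1, ..., em]``; band ``i`` covers
    ``[e_i, e_{i+1})``.  Lookups above the top edge clamp to the top band
    (the convention used for lifetable-style inputs); lookups below the
    bottom edge raise.
    """

    edges: List[float]
    female: List[float]
    male: List[float]

    @model_validator(mode="after")
    def _check(self) -> "AgeBandTable":
        if len(self.edges) < 2:
            raise ValueError("AgeBandTable needs at least two edges")
        if any(b <= a for a, b in zip(self.edges, self.edges[1:])):
            raise ValueError("AgeBandTable edges must be strictly increasing")
        nb = len(self.edges) - 1
        if len(self.female) != nb or len(self.male) != nb:
            raise ValueError(
                f"AgeBandTable needs {nb} values per sex, got "
                f"{len(self.female)}/{len(self.male)}"
            )
        return self

    # -- array-layer helpers -------------------------------------------------
    def values_matrix(self) -> np.ndarray:
        """(2, n_bands) array indexed by sex code then band."""
        return np.asarray([self.female, self.male], dtype=float)

    def band_index(self, age: np.ndarray, clamp_top: bool = True) -> np.ndarray:
        age = np.asarray(age, dtype=float)
        edges = np.asarray(self.edges)
        if np.any(age < edges[0]):
            raise ConfigError(
                f"age below table bottom edge {edges[0]}: min={age.min()}"
            )
        idx = np.searchsorted(edges, age, side="right") - 1
        top = len(edges) - 2
        if clamp_top:
            return np.minimum(idx, top)
        if np.any(idx > top):
            raise ConfigError(
                f"age above table top edge {edges[-1]}: max={np.max(age)}"
            )
        return idx

    def lookup(self, age, sex_code, clamp_top: bool = True) -> np.ndarray:
        """Vectorised value lookup; ``sex_code`` uses 0=female, 1=male."""
        idx = self.band_index(np.asarray(age, dtype=float), clamp_top=clamp_top)
        return self.values_matrix()[np.asarray(sex_code, dtype=int), idx]

    def check_probabilities(self, name: str) -> None:
        vals = self.values_matrix()
        if np.any(vals < 0) or np.any(vals > 1):
            raise ConfigError(f"{name}: probabilities must lie in [0, 1]")


class SexParams(BaseModel):
    """Marginal risk-factor distributions for one sex."""

    sbp_mean: float = Field(gt=0)
    sbp_sd: float = Field(gt=0)
    sbp_bounds: Tuple[float, float] = (80.0, 240.0)
    bmi_mean: float = Field(gt=0)
    bmi_sd: float = Field(gt=0)
    smoking_prev: float = Field(ge=0, le=1)

    @model_validator(mode="after")
    def _check(self) -> "SexParams":
        lo, hi = self.sbp_bounds
        if not lo < hi:
            raise ValueError("sbp_bounds must satisfy lo < hi")
        return self


class PopulationConfig(BaseModel):
    """Synthetic cohort structure: adults 40-69 with SBP, BMI, smoking."""

    cohort_size: int = Field(default=10_000, ge=0, description="per sex")
    age_range: Tuple[float, float] = (40.0, 69.0)
    female: SexParams
    male: SexParams
    target_hypertension_prevalence: Optional[float] = Field(
        default=None, ge=0.0, le=1.0,
        description="fraction with SBP >= 140 mmHg; None keeps configured means",
    )
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "PopulationConfig":
        lo, hi = self.age_range
        if not (lo < hi):
            raise ValueError("age_range must satisfy lo < hi")
        return self


class TrajectoryConfig(BaseModel):
    """Secular SBP drift: a linear mmHg/year slope per sex and baseline-SBP band.

    ``sbp_band_edges`` partitions baseline SBP; slopes are applied once every
    12 cycles.  A deliberately simple, monotone stand-in for longitudinal
    blood-pressure trajectory models; replace via config for anything richer.
    """

    sbp_band_edges: List[float] = [0.0, 140.0, 160.0, 180.0]
    slope_female: List[float] = [0.5, 0.6, 0.7, 0.8]
    slope_male: List[float] = [0.5, 0.6, 0.7, 0.8]

    @model_validator(mode="after")
    def _check(self) -> "TrajectoryConfig":
        nb = len(self.sbp_band_edges)
        if len(self.slope_female) != nb or len(self.slope_male) != nb:
            raise ValueError("one slope per SBP band per sex required")
        if any(b <= a for a, b in zip(self.sbp_band_edges, self.sbp_band_edges[1:])):
            raise ValueError("sbp_band_edges must be strictly increasing")
        return self

    def slope(self, sex_code, baseline_sbp) -> np.ndarray:
        edges = np.asarray(self.sbp_band_edges)
        idx = np.clip(np.searchsorted(edges, baseline_sbp, side="right") - 1,
                      0, len(edges) - 1)
        mat = np.asarray([self.slope_female, self.slope_male])
        return mat[np.asarray(sex_code, dtype=int), idx]


class RiskModelConfig(BaseModel):
    """Proportional-hazards 10-year CVD risk surface.

    ``baseline`` holds the 10-year cumulative first-event risk at the
    reference covariates; log-hazard coefficients shift it per mmHg SBP,
    per kg/m² BMI and for smoking.  ``risk_multiplier`` scales the resulting
    10-year risk (0.8 reproduces the "baseline risk reduced by 20%"
    sensitivity condition).
    """

    baseline: AgeBandTable
    coef_sbp: float = 0.016
    coef_bmi: float = 0.015
    coef_smoker: float = 0.30
    ref_sbp: float = 130.0
    ref_bmi: float = 24.0
    risk_multiplier: float = Field(default=1.0, gt=0)

    @model_validator(mode="after")
    def _check(self) -> "RiskModelConfig":
        self.baseline.check_probabilities("risk_model.baseline")
        return self


class EventSplitConfig(BaseModel):
    """P(the first/recurrent-from-well CVD event is an MI | event), by age/sex."""

    p_mi: AgeBandTable

    @model_validator(mode="after")
    def _check(self) -> "EventSplitConfig":
        self.p_mi.check_probabilities("event_split.p_mi")
        return self


class TreatmentEffectConfig(BaseModel):
    """Relative risks of first CVD events on antihypertensive medication.

    Tables are (age band × baseline-SBP band); partial adherence scales the
    full effect linearly with the compliance fraction ``c``:
    ``RR_partial = 1 - c * (1 - RR_full)``.
    """

    age_edges: List[float] = [40.0, 50.0, 60.0, 70.0, 120.0]
    sbp_edges: List[float] = [140.0, 160.0, 180.0]
    rr_ihd: List[List[float]]
    rr_stroke: List[List[float]]
    compliance_fraction: float = Field(default=0.503)

    @model_validator(mode="after")
    def _check(self) -> "TreatmentEffectConfig":
        if not 0.0 <= self.compliance_fraction <= 1.0:
            raise ValueError("compliance_fraction must lie in [0, 1]")
        na, ns = len(self.age_edges) - 1, len(self.sbp_edges)
        for name, tab in (("rr_ihd", self.rr_ihd), ("rr_stroke", self.rr_stroke)):
            if len(tab) != na or any(len(row) != ns for row in tab):
                raise ValueError(f"{name} must be {na}x{ns}")
            arr = np.asarray(tab)
            if np.any(arr <= 0) or np.any(arr > 1):
                raise ValueError(f"{name} values must lie in (0, 1]")
        return self


class CascadeConfig(BaseModel):
    """Baseline care-cascade sub-proportions (status-quo India estimates)."""

    awareness: float = Field(default=0.408, ge=0, le=1)
    initiation: float = Field(default=0.777, ge=0, le=1)
    persistence: float = Field(default=0.61, ge=0, le=1)
    compliance: float = Field(default=0.503, ge=0, le=1)


class LadderStep(BaseModel):
    """One rung of the drug-titration ladder, keyed by baseline SBP."""

    step: int = Field(ge=0)
    sbp_min: float = Field(ge=0)
    annual_cost_public: float = Field(ge=0)
    annual_cost_private: float = Field(ge=0)


class TransitionConfig(BaseModel):
    """Event, fatality, recurrence and background-mortality probabilities."""

    mi_30d_fatality: AgeBandTable
    stroke_30d_fatality_female: float = Field(default=0.12, ge=0, le=1)
    stroke_30d_fatality_male: float = Field(default=0.13, ge=0, le=1)
    reinfarction_30d: float = Field(default=0.0120, ge=0, le=1)
    stroke_after_mi_30d: float = Field(default=0.0060, ge=0, le=1)
    repeat_stroke_30d: float = Field(default=0.15, ge=0, le=1)
    ihd_monthly_mortality: AgeBandTable
    stroke_monthly_mortality: AgeBandTable
    # chronic-state recurrence risks, annual by default (converted to monthly
    # under a constant hazard); set chronic_recurrence_is_annual=False if a
    # table already holds monthly values
    chronic_ihd_reinfarction: float = Field(default=0.079, ge=0, le=1)
    chronic_ihd_stroke: float = Field(default=0.014, ge=0, le=1)
    chronic_stroke_mi: float = Field(default=0.043, ge=0, le=1)
    chronic_stroke_stroke: float = Field(default=0.037, ge=0, le=1)
    chronic_recurrence_is_annual: bool = True
    rr_multi_event_fatality: float = Field(default=1.5, ge=0)
    non_cvd_death_annual: AgeBandTable

    @model_validator(mode="after")
    def _check(self) -> "TransitionConfig":
        self.mi_30d_fatality.check_probabilities("transitions.mi_30d_fatality")
        self.ihd_monthly_mortality.check_probabilities("transitions.ihd_monthly_mortality")
        self.stroke_monthly_mortality.check_probabilities(
            "transitions.stroke_monthly_mortality")
        self.non_cvd_death_annual.check_probabilities("transitions.non_cvd_death_annual")
        return self


class CostConfig(BaseModel):
    """Unit costs (US$ unless ``currency='INR'``)."""

    currency: Literal["USD", "INR"] = "USD"
    exchange_rate: float = Field(default=70.0, gt=0, description="INR per USD")
    opd_visit: float = Field(default=1.94, ge=0)
    opd_visits_per_year: float = Field(default=4.0, ge=0)
    diagnostics_once: float = Field(default=2.27, ge=0)
    programmatic_per_capita_annual: float = Field(default=0.13, ge=0)
    mi_inpatient: float = Field(default=1040.0, ge=0)
    stroke_inpatient: float = Field(default=940.0, ge=0)
    secondary_med_annual_public: Tuple[float, float] = (92.0, 184.0)
    secondary_med_annual_private: Tuple[float, float] = (227.0, 454.0)
    ihd_opd_annual: float = Field(default=45.0, ge=0)
    stroke_opd_annual: float = Field(default=67.0, ge=0)
    medication_cost_multiplier: float = Field(default=1.0, ge=0)
    programmatic_cost_multiplier: float = Field(default=1.0, ge=0)

    @model_validator(mode="after")
    def _check(self) -> "CostConfig":
        for pair in (self.secondary_med_annual_public, self.secondary_med_annual_private):
            if any(v < 0 for v in pair):
                raise ValueError("secondary medication costs must be >= 0")
        if self.currency == "INR":
            r = self.exchange_rate
            for field in ("opd_visit", "diagnostics_once", "programmatic_per_capita_annual",
                          "mi_inpatient", "stroke_inpatient", "ihd_opd_annual",
                          "stroke_opd_annual"):
                setattr(self, field, getattr(self, field) / r)
            self.secondary_med_annual_public = tuple(
                v / r for v in self.secondary_med_annual_public)
            self.secondary_med_annual_private = tuple(
                v / r for v in self.secondary_med_annual_private)
            self.currency = "USD"
        return self


class DisabilityWeightsConfig(BaseModel):
    """GBD-style disability weights for acute and chronic CVD states."""

    acute_mi: float = Field(default=0.432, ge=0, le=1)
    acute_stroke: float = Field(default=0.570, ge=0, le=1)
    acute_second_plus: float = Field(default=0.985, ge=0, le=1)
    chronic_ihd: float = Field(default=0.08, ge=0, le=1)
    chronic_stroke: float = Field(default=0.135, ge=0, le=1)
    chronic_multi: float = Field(default=0.242, ge=0, le=1)
    medication_daily: float = Field(default=0.049, ge=0, le=1)


class EconomicsConfig(BaseModel):
    discount_rate: float = Field(default=0.03, ge=0)
    gdp_per_capita: float = Field(default=2338.0, gt=0)
    national_population_40_69: float = Field(default=267.4e6, gt=0)


class ScenarioSpec(BaseModel):
    """A coverage/adherence/protocol arm of the simulation."""

    label: str = ""
    coverage: float = Field(ge=0, le=1)
    adherence: float = Field(ge=0, le=1)
    protocol: Protocol = "IHCI_simplified"
    public_fraction: float = Field(default=1.0, ge=0, le=1)
    medication_disutility_on: bool = False
    horizon_months: int = Field(default=240, ge=1)
    # the per-capita programmatic running cost applies to arms that operate
    # the intervention program; it is flat in coverage/adherence and absent
    # from the pre-intervention status quo
    programmatic_cost_on: bool = True


class ParameterDistribution(BaseModel):
    """A point estimate with a 95% CI and a sampling family for the PSA.

    ``target`` is a dotted attribute path into the bundle (e.g.
    ``"transitions.reinfarction_30d"``).
    """

    name: str
    target: str
    point: float
    lower95: float
    upper95: float
    family: Literal["beta", "gamma", "fixed"] = "beta"

    @model_validator(mode="after")
    def _check(self) -> "ParameterDistribution":
        if not self.lower95 <= self.point <= self.upper95:
            raise ValueError(
                f"{self.name}: need lower95 <= point <= upper95, got "
                f"({self.lower95}, {self.point}, {self.upper95})")
        if self.family == "beta" and not (0 <= self.lower95 and self.upper95 <= 1):
            raise ValueError(f"{self.name}: beta family requires values in [0, 1]")
        return self


class ConfigBundle(BaseModel):
    """The complete, validated model input set."""

    population: PopulationConfig
    trajectory: TrajectoryConfig = TrajectoryConfig()
    risk_model: RiskModelConfig
    event_split: EventSplitConfig
    treatment_effect: TreatmentEffectConfig
    cascade: CascadeConfig = CascadeConfig()
    ladder: List[LadderStep]
    transitions: TransitionConfig
    costs: CostConfig = CostConfig()
    disability_weights: DisabilityWeightsConfig = DisabilityWeightsConfig()
    lifetable: AgeBandTable
    economics: EconomicsConfig = EconomicsConfig()
    scenarios: Dict[str, ScenarioSpec] = {}
    psa: List[ParameterDistribution] = []

    @model_validator(mode="after")
    def _check(self) -> "ConfigBundle":
        if not self.ladder:
            raise ValueError("ladder must define at least one step")
        steps = sorted(self.ladder, key=lambda s: s.sbp_min)
        if steps[0].sbp_min != 0:
            raise ValueError("ladder must start with an sbp_min=0 (untreated) step")
        if [s.step for s in steps] != list(range(len(steps))):
            raise ValueError("ladder steps must number 0..k in order of sbp_min")
        self.ladder = steps
        for name, sc in self.scenarios.items():
            if not sc.label:
                sc.label = name
        return self

    # -- persistence ---------------------------------------------------------
    def to_yaml(self) -> str:
        """Canonical YAML serialisation (sorted keys, plain types)."""
        return yaml.safe_dump(self.model_dump(mode="json"), sort_keys=True)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_yaml())

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()


def ladder_from_csv(path) -> List[LadderStep]:
    """Read a drug ladder from CSV with columns
    (step, sbp_min, annual_cost_public, annual_cost_private)."""
    import pandas as pd
    df = pd.read_csv(path)
    return [LadderStep(**row) for row in df.to_dict("records")]


def rr_tables_from_csv(path, age_edges: List[float], sbp_edges: List[float],
                       compliance_fraction: float = 0.503) -> TreatmentEffectConfig:
    """Read medication relative-risk tables from CSV with columns
    (age_band, sbp_band, rr_ihd, rr_stroke); band columns are 0-based indices
    into the supplied edges."""
    import pandas as pd
    df = pd.read_csv(path)
    na, ns = len(age_edges) - 1, len(sbp_edges)
    ihd = [[float("nan")] * ns for _ in range(na)]
    stroke = [[float("nan")] * ns for _ in range(na)]
    for row in df.itertuples():
        ihd[int(row.age_band)][int(row.sbp_band)] = float(row.rr_ihd)
        stroke[int(row.age_band)][int(row.sbp_band)] = float(row.rr_stroke)
    if any(np.isnan(v) for tab in (ihd, stroke) for r in tab for v in r):
        raise ConfigError(f"{path}: relative-risk table has missing cells")
    return TreatmentEffectConfig(age_edges=age_edges, sbp_edges=sbp_edges,
                                 rr_ihd=ihd, rr_stroke=stroke,
                                 compliance_fraction=compliance_fraction)


def age_band_table_from_csv(path) -> AgeBandTable:
    """Read an age/sex table from CSV with columns (age_min, female, male);
    a final row's age_min plus the preceding band width closes the top edge."""
    import pandas as pd
    df = pd.read_csv(path).sort_values("age_min")
    edges = df["age_min"].tolist()
    width = edges[-1] - edges[-2] if len(edges) > 1 else 5.0
    edges = edges + [edges[-1] + width]
    return AgeBandTable(edges=edges, female=df["female"].tolist(),
                        male=df["male"].tolist())


def load_config(path) -> ConfigBundle:
    """Load and validate a YAML config bundle.

    Raises :class:`ConfigError` naming the offending field on validation
    failure.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    try:
        return ConfigBundle.model_validate(raw)
    except Exception as exc:  # pydantic.ValidationError carries field names
        raise ConfigError(str(exc)) from exc
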