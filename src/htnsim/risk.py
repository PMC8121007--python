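"""Cardiovascular event risk and the treatment effect on it.

The 10-year first-event risk follows a proportional-hazards surface in the
Globorisk-office spirit: a baseline cumulative risk by age band and sex at
reference covariates, shifted on the log-hazard scale by systolic blood
pressure, BMI and smoking,

    risk = 1 - S0(age, sex) ** exp(b_sbp*(sbp-ref) + b_bmi*(bmi-ref) + b_smk*smk)

The shipped baseline surface is a synthetic calibration with plausible
magnitudes for Indian adults; the coefficients and surface are fully
config-driven so a published equation can be dropped in.

Antihypertensive medication multiplies event risk by a relative risk looked
up by age band and *baseline* SBP band, separately for IHD and stroke.
Partial adherence scales efficacy linearly with the compliance fraction c:
``RR_partial = 1 - c * (1 - RR_full)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import (FEMALE, MALE, ConfigError, EventSplitConfig,
                     RiskModelConfig, TreatmentEffectConfig)

MONTHS_IN_TEN_YEARS = 120

ADHERENCE_NONE, ADHERENCE_PARTIAL, ADHERENCE_FULL = 0, 1, 2
_ADHERENCE_CODES = {"none": ADHERENCE_NONE, "partial": ADHERENCE_PARTIAL,
                    "full": ADHERENCE_FULL}


def _sex_code(sex) -> np.ndarray:
    if isinstance(sex, str):
        return np.asarray(MALE if sex == "male" else FEMALE)
    return np.asarray(sex, dtype=int)


@dataclass
class RiskModel:
    """Compiled proportional-hazards risk surface."""

    config: RiskModelConfig

    def ten_year_risk(self, age, sex, sbp, bmi, smoker) -> np.ndarray:
        """Vectorised 10-year first-CVD-event probability in [0, 1].

        Ages outside the configured surface raise rather than extrapolate.
        """
        cfg = self.config
        base = cfg.baseline.lookup(age, _sex_code(sex), clamp_top=False)
        lp = (cfg.coef_sbp * (np.asarray(sbp, float) - cfg.ref_sbp)
              + cfg.coef_bmi * (np.asarray(bmi, float) - cfg.ref_bmi)
              + cfg.coef_smoker * np.asarray(smoker, float))
        risk = 1.0 - (1.0 - base) ** np.exp(lp)
        return np.clip(risk * cfg.risk_multiplier, 0.0, 1.0)


def ten_year_risk(profile, model: RiskModel) -> float:
    """10-year CVD risk for a single :class:`IndividualProfile`."""
    return float(model.ten_year_risk(profile.age, profile.sex, profile.sbp,
                                     profile.bmi, profile.smoker))


def risk_to_monthly_prob(p10) -> np.ndarray | float:
    """Convert a 10-year cumulative probability to a constant-hazard monthly one.

    ``p_month = 1 - (1 - p10)^(1/120)``; exact inverse over 120 cycles.
    """
    arr = np.asarray(p10, dtype=float)
    if np.any(arr < 0) or np.any(arr > 1):
        raise ValueError("p10 must lie in [0, 1]")
    out = 1.0 - (1.0 - arr) ** (1.0 / MONTHS_IN_TEN_YEARS)
    return float(out) if np.isscalar(p10) or arr.ndim == 0 else out


@dataclass
class EventTypeSplit:
    """P(MI | CVD event) by age band and sex; stroke takes the complement."""

    config: EventSplitConfig

    def p_mi(self, age, sex) -> np.ndarray:
        return self.config.p_mi.lookup(age, _sex_code(sex), clamp_top=True)


def draw_event_type(age, sex, split: EventTypeSplit,
                    rng: np.random.Generator) -> str:
    """Bernoulli draw of the event type for one individual: 'MI' or 'stroke'."""
    p = float(split.p_mi(age, sex))
    return "MI" if rng.random() < p else "stroke"


@dataclass
class TreatmentEffect:
    """Compiled medication relative-risk lookup."""

    config: TreatmentEffectConfig

    def _band_indices(self, age, baseline_sbp):
        cfg = self.config
        age = np.asarray(age, float)
        sbp = np.asarray(baseline_sbp, float)
        a_edges = np.asarray(cfg.age_edges)
        s_edges = np.asarray(cfg.sbp_edges)
        if np.any(age < a_edges[0]) or np.any(age >= a_edges[-1]):
            raise ConfigError("age outside treatment-effect lookup")
        if np.any(sbp < s_edges[0]):
            raise ConfigError("baseline SBP below treated range")
        ai = np.searchsorted(a_edges, age, side="right") - 1
        si = np.minimum(np.searchsorted(s_edges, sbp, side="right") - 1,
                        len(s_edges) - 1)
        return ai, si

    def full_rr(self, age, baseline_sbp) -> tuple[np.ndarray, np.ndarray]:
        ai, si = self._band_indices(age, baseline_sbp)
        return (np.asarray(self.config.rr_ihd)[ai, si],
                np.asarray(self.config.rr_stroke)[ai, si])


def partial_rr(rr_full, compliance_fraction: float) -> np.ndarray:
    """Linear adherence-efficacy relation: ``1 - c * (1 - RR_full)``."""
    c = compliance_fraction
    if not 0.0 <= c <= 1.0:
        raise ValueError("compliance fraction must lie in [0, 1]")
    return 1.0 - c * (1.0 - np.asarray(rr_full, float))


def effective_rr(effect: TreatmentEffect, age, baseline_sbp,
                 adherence_class: str) -> tuple[float, float]:
    """(rr_ihd, rr_stroke) for one individual under an adherence class.

    'none' returns (1, 1); 'full' the table values; 'partial' the convex
    combination ``1 - c*(1 - RR_full)`` componentwise.
    """
    if adherence_class not in _ADHERENCE_CODES:
        raise ValueError(f"unknown adherence class {adherence_class!r}")
    if adherence_class == "none":
        return 1.0, 1.0
    rr_i, rr_s = effect.full_rr(age, baseline_sbp)
    if adherence_class == "partial":
        c = effect.config.compliance_fraction
        rr_i, rr_s = partial_rr(rr_i, c), partial_rr(rr_s, c)
    return float(rr_i), float(rr_s)


def effective_rr_arrays(effect: TreatmentEffect, age, baseline_sbp,
                        adherence_class: np.ndarray
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised :func:`effective_rr`; ``adherence_class`` uses the 0/1/2 codes.

    Untreated entries may carry any SBP (no lookup performed for them).
    """
    cls = np.asarray(adherence_class, dtype=int)
    n = cls.shape[0]
    rr_i = np.ones(n)
    rr_s = np.ones(n)
    treated = cls != ADHERENCE_NONE
    if np.any(treated):
        fi, fs = effect.full_rr(np.asarray(age, float)[treated],
                                np.asarray(baseline_sbp, float)[treated])
        c = effect.config.compliance_fraction
        part = cls[treated] == ADHERENCE_PARTIAL
        fi = np.where(part, partial_rr(fi, c), fi)
        fs = np.where(part, partial_rr(fs, c), fs)
        rr_i[treated] = fi
        rr_s[treated] = fs
    return rr_i, rr_s
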