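"""Treatment eligibility protocols and the coverage/adherence care cascade.

Coverage (fraction of eligible hypertensive individuals initiated on
treatment) factors as awareness × initiation; adherence (fraction of
initiated individuals taking medication as prescribed) factors as
persistence × high compliance.  Scenario targets for the two products are
split over their sub-proportions by scaling both by a common multiplier
relative to the status-quo baseline — preserving the baseline ratio on the
log scale — capping at 1 when one factor saturates.

Eligibility protocols:

* ``IHCI_simplified`` — SBP >= 140 mmHg (simplified titration protocol).
* ``NPCDCS`` — SBP >= 180 mmHg or 10-year CVD risk > 20% (status quo).

Cascade positions are drawn once at baseline through dedicated CRN slots, so
raising a coverage or adherence target enrolls a superset of individuals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List

import numpy as np
import pandas as pd

from . import rng as crn
from .config import CascadeConfig, ConfigError, LadderStep, ScenarioSpec
from .population import HYPERTENSION_SBP, Cohort
from .risk import ADHERENCE_FULL, ADHERENCE_NONE, ADHERENCE_PARTIAL

BaselineCascade = CascadeConfig  # domain alias

SECTOR_PUBLIC, SECTOR_PRIVATE = 0, 1


def eligible_mask(sbp, ten_year_risk, protocol: str) -> np.ndarray:
    """Vectorised protocol eligibility from SBP and 10-year CVD risk."""
    sbp = np.asarray(sbp, float)
    risk = np.asarray(ten_year_risk, float)
    if np.any(risk < 0) or np.any(risk > 1):
        raise ValueError("ten_year_risk must lie in [0, 1]")
    if protocol == "IHCI_simplified":
        return sbp >= HYPERTENSION_SBP
    if protocol == "NPCDCS":
        return (sbp >= 180.0) | (risk > 0.20)
    raise ConfigError(f"unknown protocol {protocol!r}")


def is_eligible(profile, protocol: str, ten_year_risk: float) -> bool:
    """Protocol eligibility for one individual."""
    return bool(eligible_mask(profile.sbp, ten_year_risk, protocol))


def factorize_target(target: float, baseline_pair: tuple[float, float]
                     ) -> tuple[float, float]:
    """Split a product target over two sub-proportions.

    Scales both baseline factors by the common multiplier
    ``sqrt(target / (a*b))`` (ratio-preserving on the log scale); if one
    factor would exceed 1 it is capped there and the other carries the
    remainder, so the product equals ``target`` exactly.
    """
    a, b = baseline_pair
    if not 0.0 <= target <= 1.0:
        raise ValueError("target must lie in [0, 1]")
    if not (0.0 < a <= 1.0 and 0.0 < b <= 1.0):
        raise ValueError("baseline factors must lie in (0, 1]")
    if target == 0.0:
        return 0.0, 0.0
    m = np.sqrt(target / (a * b))
    a2, b2 = a * m, b * m
    if a2 > 1.0:
        a2, b2 = 1.0, target
    elif b2 > 1.0:
        a2, b2 = target, 1.0
    return float(a2), float(b2)


@dataclass
class CascadeState:
    """One individual's position in the care cascade."""

    aware: bool
    eligible: bool
    initiated: bool
    persistent: bool
    compliant: bool
    adherence_class: str     # "full" | "partial" | "none"
    protocol_step: int
    sector: str              # "public" | "private"


@dataclass
class CascadeStates:
    """Struct-of-arrays cascade assignment for a whole cohort."""

    aware: np.ndarray
    eligible: np.ndarray
    initiated: np.ndarray
    persistent: np.ndarray
    compliant: np.ndarray
    adherence_class: np.ndarray   # int codes: 0 none, 1 partial, 2 full
    protocol_step: np.ndarray
    sector: np.ndarray            # 0 public, 1 private

    def __len__(self) -> int:
        return len(self.aware)

    def __getitem__(self, i: int) -> CascadeState:
        cls = {ADHERENCE_NONE: "none", ADHERENCE_PARTIAL: "partial",
               ADHERENCE_FULL: "full"}[int(self.adherence_class[i])]
        return CascadeState(
            aware=bool(self.aware[i]), eligible=bool(self.eligible[i]),
            initiated=bool(self.initiated[i]), persistent=bool(self.persistent[i]),
            compliant=bool(self.compliant[i]), adherence_class=cls,
            protocol_step=int(self.protocol_step[i]),
            sector="public" if self.sector[i] == SECTOR_PUBLIC else "private",
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "aware": self.aware, "eligible": self.eligible,
            "initiated": self.initiated, "persistent": self.persistent,
            "compliant": self.compliant,
            "adherence_class": self.adherence_class,
            "protocol_step": self.protocol_step, "sector": self.sector,
        })


def protocol_step_for(baseline_sbp, ladder: List[LadderStep]) -> np.ndarray | int:
    """Map baseline SBP to the drug-ladder step (0 = untreated band).

    Monotone by construction: ladder steps are sorted by their SBP cut-point.
    """
    sbp = np.asarray(baseline_sbp, float)
    if np.any(sbp <= 0):
        raise ValueError("baseline_sbp must be > 0")
    cuts = np.asarray([s.sbp_min for s in ladder])
    idx = np.searchsorted(cuts, sbp, side="right") - 1
    return int(idx) if np.isscalar(baseline_sbp) else idx


def apply_cascade(cohort: Cohort, scenario: ScenarioSpec,
                  baseline: BaselineCascade, risks: np.ndarray,
                  seed: int, ladder: List[LadderStep]) -> CascadeStates:
    """Assign every individual a cascade position for one scenario arm.

    Awareness and initiation hit the coverage target among eligible
    hypertensive individuals; persistence and compliance hit the adherence
    target among the initiated.  Draws go through fixed CRN slots so arms
    sharing a master seed nest into each other.
    """
    n = len(cohort)
    risks = np.asarray(risks, float)
    if len(risks) != n:
        raise ValueError("risks must align with the cohort")

    aware_p, init_p = factorize_target(
        scenario.coverage, (baseline.awareness, baseline.initiation))
    persist_p, comply_p = factorize_target(
        scenario.adherence, (baseline.persistence, baseline.compliance))

    u_aware = crn.uniform_array(seed, 0, crn.SLOT_AWARE, n)
    u_init = crn.uniform_array(seed, 0, crn.SLOT_INITIATE, n)
    u_pers = crn.uniform_array(seed, 0, crn.SLOT_PERSIST, n)
    u_comp = crn.uniform_array(seed, 0, crn.SLOT_COMPLY, n)
    u_sect = crn.uniform_array(seed, 0, crn.SLOT_SECTOR, n)

    eligible = eligible_mask(cohort.baseline_sbp, risks, scenario.protocol)
    hypertensive = cohort.hypertensive
    aware = u_aware < aware_p
    initiated = aware & eligible & hypertensive & (u_init < init_p)
    persistent = initiated & (u_pers < persist_p)
    compliant = persistent & (u_comp < comply_p)

    adherence_class = np.full(n, ADHERENCE_NONE, dtype=np.int8)
    adherence_class[persistent] = ADHERENCE_PARTIAL
    adherence_class[compliant] = ADHERENCE_FULL

    step = np.where(initiated, protocol_step_for(cohort.baseline_sbp, ladder), 0)
    sector = np.where(u_sect < scenario.public_fraction,
                      SECTOR_PUBLIC, SECTOR_PRIVATE).astype(np.int8)
    return CascadeStates(aware=aware, eligible=eligible, initiated=initiated,
                         persistent=persistent, compliant=compliant,
                         adherence_class=adherence_class,
                         protocol_step=step.astype(np.int8), sector=sector)
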