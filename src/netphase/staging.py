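"""Atrophy staging: W-scores, binarization, and five-phase assignment.

A W-score standardizes a patient's regional grey-matter volume against a
control regression on age and intracranial volume:

    W = (observed - predicted) / residual SD

Volumes are binarized at W < -0.5 (strict), and regions are sorted into
phases by the ratio N_a(r) / N_m, where N_a(r) is the number of patients in
the group with atrophy in region r and N_m its maximum over regions:
ratio >= 0.9 -> phase 1 (epicentre), [0.8, 0.9) -> 2, [0.7, 0.8) -> 3,
[0.6, 0.7) -> 4, [0.5, 0.6) -> 5, below 0.5 -> unassigned.  Exact ratios are
used; nothing is rounded to integer percentages.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np

from .model import Cohort, SubjectRecord

logger = logging.getLogger(__name__)

__all__ = [
    "WScoreModel",
    "AtrophyTable",
    "PhaseAssignment",
    "fit_wscore_model",
    "compute_wscores",
    "binarize_atrophy",
    "assign_phases",
    "stage_cohort",
]

UNASSIGNED = 0  # phase code for regions with rare atrophy (ratio < 0.5)

# half-open ratio bins [low, high) per phase; phase 1 closed at 1.0
_PHASE_BINS = ((1, 0.9), (2, 0.8), (3, 0.7), (4, 0.6), (5, 0.5))


@dataclasses.dataclass
class WScoreModel:
    """Per-region OLS of volume on age and ICV, fitted on controls."""

    intercept: np.ndarray
    age_coef: np.ndarray
    icv_coef: np.ndarray
    residual_sd: np.ndarray     # denominator n - 3
    n_fit: int

    @property
    def n_regions(self) -> int:
        return self.intercept.shape[0]

    def predict(self, age: float, icv: float) -> np.ndarray:
        return self.intercept + self.age_coef * age + self.icv_coef * icv


@dataclasses.dataclass
class AtrophyTable:
    """Binary subjects x regions atrophy matrix with per-region counts."""

    table: np.ndarray           # bool (n_subjects, n_regions)
    subject_ids: list[str]

    @property
    def n_a(self) -> np.ndarray:
        return self.table.sum(axis=0)

    @property
    def n_m(self) -> int:
        return int(self.n_a.max())


@dataclasses.dataclass
class PhaseAssignment:
    """Region -> phase 1..5 or UNASSIGNED (0)."""

    phases: np.ndarray          # int per region
    ratios: np.ndarray          # N_a(r) / N_m per region

    def regions_in_phase(self, phase: int) -> np.ndarray:
        return np.flatnonzero(self.phases == phase)

    def phase_sizes(self) -> dict[int, int]:
        return {p: int((self.phases == p).sum()) for p in range(1, 6)}


def fit_wscore_model(hc_cohort: Cohort, min_controls: int = 10) -> WScoreModel:
    """Fit per-region OLS volume ~ age + icv on the control cohort.

    Residual SD uses an n - 3 denominator (three fitted coefficients).
    Raises on a rank-deficient design (e.g. constant age across controls) or
    a degenerate zero-residual fit.
    """
    subs = hc_cohort.subjects
    if len(subs) < min_controls:
        raise ValueError(f"need >= {min_controls} controls, got {len(subs)}")
    age = np.array([s.age for s in subs])
    icv = np.array([s.icv for s in subs])
    X = np.column_stack([np.ones(len(subs)), age, icv])
    if np.linalg.matrix_rank(X) < 3:
        bad = "age" if np.ptp(age) == 0 else "icv"
        raise ValueError(f"rank-deficient W-score design: covariate {bad!r} "
                         "is constant across controls")
    V = hc_cohort.volumes_matrix()                     # (n_subj, n_regions)
    coef, _, _, _ = np.linalg.lstsq(X, V, rcond=None)  # (3, n_regions)
    resid = V - X @ coef
    sd = np.sqrt((resid ** 2).sum(axis=0) / (len(subs) - 3))
    if np.any(sd <= 1e-8 * np.abs(V).mean()):
        r = int(np.argmin(sd))
        raise ValueError(f"zero residual SD in region index {r}: volumes are "
                         "exactly linear in age/icv (degenerate fit)")
    return WScoreModel(intercept=coef[0], age_coef=coef[1], icv_coef=coef[2],
                       residual_sd=sd, n_fit=len(subs))


def compute_wscores(subject: SubjectRecord, model: WScoreModel) -> np.ndarray:
    """Per-region W = (observed - predicted) / residual SD."""
    if subject.volumes.shape[0] != model.n_regions:
        raise ValueError(
            f"subject {subject.subject_id!r} has {subject.volumes.shape[0]} "
            f"regions, model expects {model.n_regions}")
    return (subject.volumes - model.predict(subject.age, subject.icv)) \
        / model.residual_sd


def binarize_atrophy(w: np.ndarray, threshold: float = -0.5) -> np.ndarray:
    """Atrophy indicator: strictly W < threshold."""
    return np.asarray(w) < threshold


def assign_phases(atrophy: AtrophyTable | np.ndarray) -> PhaseAssignment:
    """Bin regions into phases 1..5 by the exact ratio N_a(r) / N_m."""
    table = atrophy.table if isinstance(atrophy, AtrophyTable) else np.asarray(atrophy)
    n_a = table.sum(axis=0)
    n_m = n_a.max()
    if n_m == 0:
        raise ValueError("no region shows atrophy in any subject; nothing to stage")
    ratio = n_a / n_m
    phases = np.full(ratio.shape, UNASSIGNED, dtype=int)
    for phase, low in _PHASE_BINS:
        phases[(ratio >= low) & (phases == UNASSIGNED)] = phase
    return PhaseAssignment(phases=phases, ratios=ratio)


def stage_cohort(patients: Cohort, model: WScoreModel,
                 threshold: float = -0.5) -> tuple[AtrophyTable, PhaseAssignment, np.ndarray]:
    """W-score, binarize and phase a patient cohort against a control model.

    Patients lacking age or ICV are excluded with a logged warning.  Returns
    the atrophy table, the phase assignment and the W-score matrix.
    """
    usable, ws = [], []
    for s in patients.subjects:
        if not np.isfinite(s.age) or not np.isfinite(s.icv):
            logger.warning("subject %s lacks covariates; excluded from staging",
                           s.subject_id)
            continue
        usable.append(s)
        ws.append(compute_wscores(s, model))
    W = np.vstack(ws)
    table = AtrophyTable(table=binarize_atrophy(W, threshold),
                         subject_ids=[s.subject_id for s in usable])
    return table, assign_phases(table), W
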