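"""Case-control edge z-scoring and weakened-edge statistics.

Each subject edge weight w is standardized against the control cohort:

    z = (w - mean_HC) / SD_HC

per edge, using only controls in whom the edge is defined.  A reference edge
is usable when at least ``min_obs`` controls contribute and the sample SD is
positive; elsewhere z is undefined rather than infinite.  An edge is
*weakened* when z <= -3 (inclusive).  Missing subject edges stay NaN and are
excluded from every count; the number of reference edges absent in a patient
is reported separately.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .hubs import HubSet
from .model import Cohort, SubjectRecord
from .staging import PhaseAssignment

__all__ = [
    "EdgeReference",
    "build_edge_reference",
    "edge_zscores",
    "weak_edges",
    "transition_edge_stats",
    "hub_connected_fraction",
    "whole_brain_mean_z",
    "node_mean_edge_z",
    "missing_reference_edges",
]

WEAK_THRESHOLD = -3.0


@dataclasses.dataclass
class EdgeReference:
    """Per-edge HC mean, sample SD and contributing-control count."""

    mean: np.ndarray      # (n, n), NaN where unusable
    sd: np.ndarray        # (n, n), NaN where unusable
    n_obs: np.ndarray     # (n, n) int
    min_obs: int

    @property
    def usable(self) -> np.ndarray:
        return ~np.isnan(self.sd)


def build_edge_reference(hc_cohort: Cohort, min_obs: int = 5) -> EdgeReference:
    """Per-edge mean/SD over controls in whom the edge is defined.

    Edges with fewer than ``min_obs`` observations or zero sample SD are
    marked unusable (NaN mean/SD).
    """
    stack = hc_cohort.connectivity_stack()          # (k, n, n)
    defined = ~np.isnan(stack)
    n_obs = defined.sum(axis=0)
    vals = np.where(defined, stack, 0.0)
    denom = np.maximum(n_obs, 1)
    mean = vals.sum(axis=0) / denom
    # sample SD, n-1 denominator, only where >= 2 observations
    ss = ((vals - np.where(defined, mean, 0.0)) ** 2).sum(axis=0)
    sd = np.sqrt(ss / np.maximum(n_obs - 1, 1))
    mean = np.where(n_obs > 0, mean, np.nan)
    sd = np.where(n_obs >= 2, sd, np.nan)
    unusable = (n_obs < min_obs) | ~(sd > 0)
    mean = np.where(unusable, np.nan, mean)
    sd = np.where(unusable, np.nan, sd)
    np.fill_diagonal(mean, np.nan)
    np.fill_diagonal(sd, np.nan)
    return EdgeReference(mean=mean, sd=sd, n_obs=n_obs.astype(int), min_obs=min_obs)


def edge_zscores(subject: SubjectRecord | np.ndarray,
                 reference: EdgeReference) -> np.ndarray:
    """Symmetric z matrix; NaN where the subject edge or reference is unusable."""
    w = subject.connectivity if isinstance(subject, SubjectRecord) else subject
    with np.errstate(invalid="ignore"):
        z = (w - reference.mean) / reference.sd
    return z


def weak_edges(zmatrix: np.ndarray, threshold: float = WEAK_THRESHOLD
               ) -> set[tuple[int, int]]:
    """Unordered node pairs with z <= threshold (inclusive)."""
    iu, ju = np.nonzero(np.triu(zmatrix <= threshold, 1))
    return {(int(i), int(j)) for i, j in zip(iu, ju)}


def missing_reference_edges(subject: SubjectRecord | np.ndarray,
                            reference: EdgeReference) -> int:
    """Count usable reference edges that are absent in this subject."""
    w = subject.connectivity if isinstance(subject, SubjectRecord) else subject
    return int((np.triu(reference.usable, 1) & np.isnan(np.triu(w, 1))).sum())


def _phase_sets(phases: PhaseAssignment, p: int, q: int):
    if p == q:
        raise ValueError("phase pair must be distinct")
    a = set(phases.regions_in_phase(p).tolist())
    b = set(phases.regions_in_phase(q).tolist())
    return a, b


def transition_edge_stats(weak_set: set[tuple[int, int]], phases: PhaseAssignment,
                          pair: tuple[int, int],
                          normalization: str = "product") -> dict[str, float | None]:
    """Cross-phase weakened-edge count for one subject and one phase pair.

    Counts weak edges with one endpoint in phase p and the other in phase q,
    then normalizes by the number of nodes in each phase (default: the
    product n_p * n_q; ``normalization="sum"`` divides by n_p + n_q).
    Returns None for the normalized value when either phase is empty.
    """
    p, q = pair
    a, b = _phase_sets(phases, p, q)
    count = sum(1 for (i, j) in weak_set
                if (i in a and j in b) or (i in b and j in a))
    if not a or not b:
        return {"count": float(count), "normalized": None}
    denom = len(a) * len(b) if normalization == "product" else len(a) + len(b)
    return {"count": float(count), "normalized": count / denom}


def hub_connected_fraction(weak_set: set[tuple[int, int]], hc_hubs: HubSet,
                           phases: PhaseAssignment, pair: tuple[int, int]
                           ) -> float | None:
    """Percent of cross-phase weak edges touching >= 1 control hub.

    None when the subject has no cross-phase weak edges for this pair.
    """
    p, q = pair
    a, b = _phase_sets(phases, p, q)
    cross = [(i, j) for (i, j) in weak_set
             if (i in a and j in b) or (i in b and j in a)]
    if not cross:
        return None
    hit = sum(1 for (i, j) in cross if i in hc_hubs.members or j in hc_hubs.members)
    return 100.0 * hit / len(cross)


def whole_brain_mean_z(zmatrix: np.ndarray) -> float | None:
    """Mean of defined z over the upper triangle; None if all missing."""
    vals = zmatrix[np.triu_indices_from(zmatrix, 1)]
    vals = vals[~np.isnan(vals)]
    return float(vals.mean()) if vals.size else None


def node_mean_edge_z(zmatrix: np.ndarray, node: int) -> float | None:
    """Mean of the node's defined incident z; None if all missing."""
    row = zmatrix[node].copy()
    row[node] = np.nan
    vals = row[~np.isnan(row)]
    return float(vals.mean()) if vals.size else None
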