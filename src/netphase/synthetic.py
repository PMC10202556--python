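"""Synthetic cohort generator with planted ground truth.

Emulates the study design of an antemortem structural-connectome comparison
of two neurodegenerative pathologies against healthy controls:

* a control (HC) cohort whose FA-like edge weights have stable per-edge
  means and SDs, distance-dependent edge missingness, and volumes linear in
  age and intracranial volume;
* disease cohorts with a planted five-phase atrophy-prevalence gradient
  radiating from an epicentre, under one of two spreading mechanisms —
  ``distant`` (spread along strong long-range connections, with long-range
  edges incident to epicentre hubs weakened by several HC SDs) or
  ``proximal`` (spread along physical region adjacency, with at most a tenth
  as many edge decrements);
* %-area-occupied (%AO) histopathology values coupled to the planted local
  edge damage so that heavier pathology co-occurs with more negative edge
  z-scores.

Every draw derives from one root integer seed via keyed substreams, so a
subject's data does not depend on cohort size.
"""

from __future__ import annotations

import dataclasses
from typing import Literal

import numpy as np
import pandas as pd
from scipy.stats import norm

from .model import Cohort, RegionAtlas, SubjectRecord

Mechanism = Literal["distant", "proximal"]

__all__ = [
    "GeneratorParams",
    "SyntheticTruth",
    "generate_atlas",
    "generate_hc_cohort",
    "generate_disease_cohort",
    "generate_histology",
]

# substream tags (integers so SeedSequence keys stay integer tuples)
_TAG_ATLAS = 1
_TAG_SKELETON = 2
_TAG_SUBJECT = 3
_TAG_PLANT = 4
_TAG_HISTO = 5


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, key)]))


@dataclasses.dataclass
class GeneratorParams:
    """Tunable generative model; defaults mirror the study conditions.

    Cohort sizes default to 27 controls and 28/13 patients for the
    distant/proximal mechanisms.  Phase prevalences are the *observed*
    (post W-binarization) atrophy prevalences relative to the epicentre;
    weakening depth ``delta`` is expressed in HC per-edge SD units and must
    exceed the z <= -3 detection threshold.
    """

    n_regions: int = 100
    n_hc: int = 27
    n_distant: int = 28        # tauopathy-like cohort size
    n_proximal: int = 13       # TDP-like cohort size

    # edge model
    conn_decay_length: float = 60.0    # mm; P(edge exists) = exp(-d / this)
    weight_base: float = 0.25          # asymptote of the mean-weight curve
    weight_span: float = 0.45          # mu(d) = base + span * exp(-d / weight_decay)
    weight_decay: float = 40.0         # mm
    sigma_w: float = 0.05              # between-subject SD of an edge weight
    miss_base: float = 0.05            # missingness at distance 0
    miss_slope: float = 0.30           # extra missingness at the max distance

    # volume model: v = a + b*age + c*icv + eta
    vol_intercept: float = 2000.0      # mm^3
    vol_age_slope: float = -8.0        # mm^3 / year
    vol_icv_slope: float = 1.5e-3      # mm^3 / mm^3
    sigma_v: float = 150.0             # mm^3 residual SD
    age_range: tuple[float, float] = (55.0, 80.0)
    icv_mean: float = 1.45e6
    icv_sd: float = 1.2e5

    # disease model
    prevalences: tuple[float, ...] = (0.95, 0.85, 0.75, 0.65, 0.55)
    atrophy_depth: float = 2.5         # volume decrement in sigma_v units
    w_threshold: float = -0.5          # binarization threshold the phases target
    delta: float = 4.0                 # edge weakening depth in HC-SD units
    proximal_edge_fraction: float = 0.10  # proximal decrements vs distant count
    phase_size_fraction: float = 0.08  # regions per phase / n_regions
    long_range_quantile: float = 0.75  # "long-range" edge distance cutoff

    # histology model
    histo_regions_per_subject: int = 9
    histo_alpha: float = 2.0           # baseline %AO
    histo_beta: float = 2.0            # %AO increase per SD of planted decrement
    histo_noise_sd: float = 0.8

    def __post_init__(self) -> None:
        p = self.prevalences
        if not all(0 < x <= 1 for x in p) or not all(a > b for a, b in zip(p, p[1:])):
            raise ValueError("prevalences must be strictly decreasing in (0, 1]")
        if self.sigma_w <= 0 or self.sigma_v <= 0:
            raise ValueError("sigma_w and sigma_v must be positive")
        # delta == 0 is the degenerate no-weakening switch; otherwise the
        # decrement must exceed the z <= -3 detection threshold
        if self.delta != 0 and self.delta <= 3:
            raise ValueError("delta must be 0 (no weakening) or exceed 3 so "
                             "planted weak edges are detectable at z <= -3")


@dataclasses.dataclass
class SyntheticTruth:
    """Planted ground truth for recovery tests."""

    planted_phase: np.ndarray            # int per region; 0 = none, 1..5 = phase
    planting_prob: np.ndarray            # per-region atrophy probability
    planted_weak_edges: dict[tuple[int, int], float]  # (i<j) -> decrement, SD units
    planted_hubs: set[int]               # high-strength nodes of the HC model
    mechanism: str
    seed: int
    planted_atrophy: np.ndarray | None = None   # bool (n_subjects, n_regions)

    def phase_regions(self, phase: int) -> np.ndarray:
        return np.flatnonzero(self.planted_phase == phase)


# ---------------------------------------------------------------------------
# Atlas
# ---------------------------------------------------------------------------

def generate_atlas(n_regions: int, seed: int) -> RegionAtlas:
    """Random parcellation: centroids in a 3-D slab, symmetrized k-NN adjacency.

    Adjacency joins mutually close centroids (k = 5 nearest neighbours,
    symmetrized); any residual components are stitched through their closest
    inter-component pair so the contiguity graph is always connected.
    """
    if n_regions < 20:
        raise ValueError("n_regions must be >= 20 for pipeline use")
    rng = _rng(seed, _TAG_ATLAS)
    # slab roughly shaped like a cortical sheet: wide, long, thin
    centroids = rng.uniform([0, 0, 0], [140.0, 110.0, 60.0], size=(n_regions, 3))
    d = np.sqrt(((centroids[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2))
    k = 5
    adjacency = np.zeros((n_regions, n_regions), dtype=bool)
    order = np.argsort(d, axis=1)
    for i in range(n_regions):
        for j in order[i, 1:k + 1]:
            adjacency[i, j] = adjacency[j, i] = True

    # stitch components (deterministic: closest pair across the split)
    comp = _components(adjacency)
    while len(set(comp)) > 1:
        main = comp == comp[0]
        dd = d.copy()
        dd[np.ix_(main, main)] = np.inf
        dd[np.ix_(~main, ~main)] = np.inf
        i, j = np.unravel_index(np.argmin(dd), dd.shape)
        adjacency[i, j] = adjacency[j, i] = True
        comp = _components(adjacency)

    mid = float(np.median(centroids[:, 0]))
    hemi = tuple("L" if x < mid else "R" for x in centroids[:, 0])
    ids = tuple(f"R{i:03d}" for i in range(n_regions))
    names = tuple(f"region_{i:03d}" for i in range(n_regions))
    return RegionAtlas(region_ids=ids, names=names, hemisphere=hemi,
                       centroids=centroids, adjacency=adjacency)


def _components(adjacency: np.ndarray) -> np.ndarray:
    from scipy.sparse.csgraph import connected_components

    _, labels = connected_components(adjacency, directed=False)
    return labels


# ---------------------------------------------------------------------------
# HC cohort
# ---------------------------------------------------------------------------

def _edge_skeleton(atlas: RegionAtlas, params: GeneratorParams, seed: int):
    """Cohort-level edge set, mean-weight matrix and missingness probabilities.

    The skeleton is shared by every cohort generated from the same seed, so
    patient edges are comparable to the HC reference edge by edge.
    """
    d = atlas.centroid_distances()
    rng = _rng(seed, _TAG_SKELETON)
    n = atlas.n_regions
    p_conn = np.exp(-d / params.conn_decay_length)
    upper = np.triu(rng.random((n, n)) < p_conn, 1)
    exists = upper | upper.T
    np.fill_diagonal(exists, False)
    mu = params.weight_base + params.weight_span * np.exp(-d / params.weight_decay)
    dmax = d[exists].max() if exists.any() else 1.0
    p_miss = np.clip(params.miss_base + params.miss_slope * d / dmax, 0.0, 0.95)
    return exists, mu, p_miss, d


def _subject_connectivity(exists, mu, p_miss, params, rng, decrement=None):
    n = exists.shape[0]
    w = np.full((n, n), np.nan)
    iu, ju = np.nonzero(np.triu(exists, 1))
    vals = np.clip(mu[iu, ju] + rng.normal(0.0, params.sigma_w, size=iu.size),
                   0.05, 1.0)
    if decrement is not None:
        vals = np.clip(vals - decrement[iu, ju], 0.01, 1.0)
    # missingness applied after weakening, so some weakened edges are absent
    miss = rng.random(iu.size) < p_miss[iu, ju]
    vals[miss] = np.nan
    w[iu, ju] = vals
    w[ju, iu] = vals
    return w


def _covariates(params: GeneratorParams, rng: np.random.Generator):
    age = rng.uniform(*params.age_range)
    icv = max(float(rng.normal(params.icv_mean, params.icv_sd)), 5e5)
    return age, icv


def _predicted_volumes(params, age, icv, n):
    return np.full(n, params.vol_intercept + params.vol_age_slope * age
                   + params.vol_icv_slope * icv)


def generate_hc_cohort(atlas: RegionAtlas, params: GeneratorParams, seed: int,
                       n_subjects: int | None = None) -> Cohort:
    """Healthy-control cohort from the null generative model."""
    n_subjects = params.n_hc if n_subjects is None else n_subjects
    exists, mu, p_miss, _ = _edge_skeleton(atlas, params, seed)
    subjects = []
    for k in range(n_subjects):
        rng = _rng(seed, _TAG_SUBJECT, 0, k)
        age, icv = _covariates(params, rng)
        vols = _predicted_volumes(params, age, icv, atlas.n_regions) \
            + rng.normal(0.0, params.sigma_v, size=atlas.n_regions)
        conn = _subject_connectivity(exists, mu, p_miss, params, rng)
        subjects.append(SubjectRecord(subject_id=f"HC{k:04d}", group="HC",
                                      age=age, icv=icv, volumes=vols,
                                      connectivity=conn))
    return Cohort(label="HC", subjects=subjects, atlas=atlas)


# ---------------------------------------------------------------------------
# Disease cohorts
# ---------------------------------------------------------------------------

def _plant_phases(atlas, params, exists, mu, d, mechanism, rng):
    """Choose the epicentre and expand phases 2..5 under the mechanism.

    ``distant``: each next phase takes the unassigned regions with the
    strongest long-reaching skeleton connections (weight x distance score) to
    the previous phase.  ``proximal``: breadth-first rings of physical
    adjacency around the epicentre.
    """
    n = atlas.n_regions
    strength = np.where(exists, mu, 0.0).sum(axis=1)
    hub_cut = strength.mean() + strength.std(ddof=1)
    planted_hubs = set(np.flatnonzero(strength > hub_cut).tolist())

    per_phase = max(3, round(params.phase_size_fraction * n))
    if mechanism == "distant":
        # the distant mechanism damages long-range projections, so its
        # epicentre is the hub with the richest long-range connectivity
        long_cut = np.quantile(d[np.triu(exists, 1)], params.long_range_quantile)
        long_degree = (exists & (d > long_cut)).sum(axis=1)
        epicentre = int(max(planted_hubs, key=lambda i: (long_degree[i], strength[i])))
    else:
        hubs_sorted = sorted(planted_hubs, key=lambda i: -strength[i])
        epicentre = int(hubs_sorted[rng.integers(0, min(3, len(hubs_sorted)))])
    phase1 = list(np.argsort(d[epicentre])[:per_phase])  # epicentre + neighbours

    planted = np.zeros(n, dtype=int)
    planted[phase1] = 1
    prev = list(phase1)
    for ph in range(2, 6):
        free = np.flatnonzero(planted == 0)
        if free.size == 0:
            break
        if mechanism == "distant":
            # expand along the strongest long-range connections from the
            # previous phase; fall back to any connection, then proximity
            long_cut = np.quantile(d[np.triu(exists, 1)], params.long_range_quantile)
            score = np.zeros(n)
            for r in free:
                conn = exists[r, prev] & (d[r, prev] > long_cut)
                if conn.any():
                    score[r] = np.max(mu[r, prev][conn])
                else:
                    anyconn = exists[r, prev]
                    if anyconn.any():
                        score[r] = 1e-3 * np.max(mu[r, prev][anyconn])
            chosen = free[np.argsort(-score[free])][:per_phase]
        else:  # proximal: adjacency rings, nearest-first
            adj_to_prev = atlas.adjacency[:, prev].any(axis=1)
            ring = [r for r in free if adj_to_prev[r]]
            ring.sort(key=lambda r: d[r, prev].min())
            chosen = ring[:per_phase]
            if len(chosen) < per_phase:   # fall back to spatial proximity
                rest = [r for r in free if r not in set(chosen)]
                rest.sort(key=lambda r: d[r, prev].min())
                chosen = list(chosen) + rest[: per_phase - len(chosen)]
        planted[list(chosen)] = ph
        prev = list(chosen)
    return planted, planted_hubs, epicentre


def _planting_probabilities(planted, params):
    """Invert the W-binarization confusion so observed prevalence hits target.

    The recovered atrophy map flips planted states with fixed rates
    (false-positive Phi(threshold), true-positive Phi(depth + threshold)), so
    the Bernoulli planting probability is the confusion-matrix inversion of
    the target prevalence.
    """
    fpr = float(norm.cdf(params.w_threshold))
    tpr = float(norm.cdf(params.atrophy_depth + params.w_threshold))
    probs = np.zeros(planted.shape[0])
    for ph, target in enumerate(params.prevalences, start=1):
        pi = (target - fpr) / (tpr - fpr)
        probs[planted == ph] = np.clip(pi, 0.0, 1.0)
    return probs


def generate_disease_cohort(
    atlas: RegionAtlas,
    params: GeneratorParams,
    mechanism: Mechanism,
    seed: int,
    n_subjects: int | None = None,
    label: str | None = None,
) -> tuple[Cohort, SyntheticTruth]:
    """Disease cohort with planted phases and mechanism-specific edge damage.

    The prevalence gradient is the designed study condition, so each region's
    atrophy count is planted as an exact quota (round(pi_r * n_subjects)
    randomly assigned subjects); every subject is equally likely to be drawn
    for a region, so the marginal per-region atrophy probability equals the
    planting probability while the gradient itself carries no sampling noise.
    Subject-level noise enters through volumes (and hence W-scores), edge
    weights and missingness.
    """
    if mechanism not in ("distant", "proximal"):
        raise ValueError(f"unknown mechanism {mechanism!r}")
    if n_subjects is None:
        n_subjects = params.n_distant if mechanism == "distant" else params.n_proximal
    if label is None:
        label = "TAU" if mechanism == "distant" else "TDP"

    exists, mu, p_miss, d = _edge_skeleton(atlas, params, seed)
    rng = _rng(seed, _TAG_PLANT, 0 if mechanism == "distant" else 1)
    planted, planted_hubs, _ = _plant_phases(atlas, params, exists, mu, d,
                                             mechanism, rng)
    probs = _planting_probabilities(planted, params)

    # candidate damaged edges: long-range skeleton edges touching phase-1 hubs
    long_cut = np.quantile(d[np.triu(exists, 1)], params.long_range_quantile)
    phase1_hubs = sorted(planted_hubs & set(np.flatnonzero(planted == 1).tolist()))
    candidates = [
        (min(i, j), max(i, j))
        for i in phase1_hubs
        for j in np.flatnonzero(exists[i])
        if d[i, j] > long_cut
    ]
    candidates = sorted(set(candidates))
    if params.delta == 0:
        candidates = []
    if mechanism == "distant":
        weak = candidates
    else:
        n_weak = int(params.proximal_edge_fraction * len(candidates))
        weak = [candidates[i] for i in
                sorted(rng.choice(len(candidates), size=n_weak, replace=False))] \
            if n_weak else []
    decrement = np.zeros_like(mu)
    for i, j in weak:
        decrement[i, j] = decrement[j, i] = params.delta * params.sigma_w
    planted_weak = {(i, j): params.delta for i, j in weak}

    group_tag = 1 if mechanism == "distant" else 2
    # exact-prevalence quota assignment (cohort-level substream)
    arng = _rng(seed, _TAG_PLANT, group_tag, 7)
    atrophy = np.zeros((n_subjects, atlas.n_regions), dtype=bool)
    for r in range(atlas.n_regions):
        quota = int(round(probs[r] * n_subjects))
        if quota:
            atrophy[arng.permutation(n_subjects)[:quota], r] = True

    subjects = []
    for k in range(n_subjects):
        srng = _rng(seed, _TAG_SUBJECT, group_tag, k)
        age, icv = _covariates(params, srng)
        atrophied = atrophy[k]
        vols = _predicted_volumes(params, age, icv, atlas.n_regions)
        vols = vols - params.atrophy_depth * params.sigma_v * atrophied \
            + srng.normal(0.0, params.sigma_v, size=atlas.n_regions)
        conn = _subject_connectivity(exists, mu, p_miss, params, srng,
                                     decrement=decrement)
        duration = float(np.round(srng.uniform(1.0, 8.0), 2))
        subjects.append(SubjectRecord(
            subject_id=f"{label}{k:04d}", group=label, age=age, icv=icv,
            disease_duration=duration, volumes=vols, connectivity=conn))

    truth = SyntheticTruth(planted_phase=planted, planting_prob=probs,
                           planted_weak_edges=planted_weak,
                           planted_hubs=planted_hubs,
                           mechanism=mechanism, seed=int(seed),
                           planted_atrophy=atrophy)
    return Cohort(label=label, subjects=subjects, atlas=atlas), truth


# ---------------------------------------------------------------------------
# Histology
# ---------------------------------------------------------------------------

def _histology_panel(truth: SyntheticTruth, n: int, m: int) -> list[int]:
    """Fixed autopsy sampling panel shared by all subjects.

    Mirrors standard-region sampling: it spans disease-implicated cortex
    (epicentre hubs, one region per planted phase) and preserved cortex
    (evenly spaced unassigned regions), deterministically from the truth.
    """
    panel: list[int] = []

    def add(r: int) -> None:
        if r not in panel and len(panel) < m:
            panel.append(int(r))

    for r in sorted(truth.planted_hubs & set(truth.phase_regions(1).tolist()))[:2]:
        add(r)
    for ph in range(1, 6):
        regs = truth.phase_regions(ph)
        if regs.size:
            add(regs[0])
    spare = np.flatnonzero(truth.planted_phase == 0)
    if spare.size:
        for r in spare[:: max(1, spare.size // max(1, m - len(panel)))]:
            add(r)
    for r in range(n):          # pad in the degenerate all-staged case
        add(r)
    return panel


def generate_histology(cohort: Cohort, truth: SyntheticTruth,
                       params: GeneratorParams, seed: int) -> pd.DataFrame:
    """%-area-occupied pathology table coupled to planted edge damage.

    A fixed panel of ~9 regions (the same for every subject, spanning
    diseased and preserved cortex) is sampled per subject; per tissue
    (GM, WM), %AO = clip(alpha + beta * D + noise, 0, 100), where D is the
    node's mean planted edge decrement in HC-SD units.  Since measured mean
    edge z at a node is approximately -D, %AO is negatively coupled to edge
    integrity.
    """
    atlas = cohort.atlas
    n = atlas.n_regions
    # node mean planted decrement over incident skeleton edges
    exists, _, _, _ = _edge_skeleton(atlas, params, truth.seed)
    dec = np.zeros((n, n))
    for (i, j), delta_sd in truth.planted_weak_edges.items():
        dec[i, j] = dec[j, i] = delta_sd
    degree = exists.sum(axis=1)
    node_dec = np.where(degree > 0, dec.sum(axis=1) / np.maximum(degree, 1), 0.0)

    panel = _histology_panel(truth, n, min(params.histo_regions_per_subject, n))
    rows = []
    for k, s in enumerate(cohort.subjects):
        rng = _rng(seed, _TAG_HISTO, k)
        for r in panel:
            for tissue in ("GM", "WM"):
                ao = params.histo_alpha + params.histo_beta * node_dec[r] \
                    + rng.normal(0.0, params.histo_noise_sd)
                rows.append({
                    "subject_id": s.subject_id,
                    "region_id": atlas.region_ids[r],
                    "tissue": tissue,
                    "pct_area_occupied": float(np.clip(ao, 0.0, 100.0)),
                })
    return pd.DataFrame(rows)
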