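"""Shared fixtures: small deterministic atlases, cohorts and matrices."""

import numpy as np
import pytest

from netphase.model import Cohort, RegionAtlas, SubjectRecord


def make_atlas(n: int = 6, seed: int = 0) -> RegionAtlas:
    """Small atlas with a ring adjacency and random centroids."""
    rng = np.random.default_rng(seed)
    adjacency = np.zeros((n, n), dtype=bool)
    for i in range(n):
        j = (i + 1) % n
        adjacency[i, j] = adjacency[j, i] = True
    return RegionAtlas(
        region_ids=tuple(f"R{i:03d}" for i in range(n)),
        names=tuple(f"region_{i}" for i in range(n)),
        hemisphere=tuple("L" if i < n // 2 else "R" for i in range(n)),
        centroids=rng.uniform(0, 100, size=(n, 3)),
        adjacency=adjacency,
    )


def random_connectivity(rng: np.random.Generator, n: int,
                        missing_frac: float = 0.2) -> np.ndarray:
    """Random symmetric weight matrix in (0, 1] with NaN missingness."""
    m = np.full((n, n), np.nan)
    iu, ju = np.triu_indices(n, 1)
    vals = rng.uniform(0.05, 1.0, size=iu.size)
    vals[rng.random(iu.size) < missing_frac] = np.nan
    m[iu, ju] = vals
    m[ju, iu] = vals
    return m


def make_subject(rng: np.random.Generator, atlas: RegionAtlas, sid: str,
                 group: str = "HC", duration: float | None = None,
                 missing_frac: float = 0.2) -> SubjectRecord:
    n = atlas.n_regions
    return SubjectRecord(
        subject_id=sid,
        group=group,
        age=float(rng.uniform(55, 80)),
        icv=float(rng.uniform(1.2e6, 1.6e6)),
        disease_duration=duration,
        volumes=rng.uniform(2000, 4000, size=n),
        connectivity=random_connectivity(rng, n, missing_frac),
    )


def make_cohort(n_subjects: int = 3, n_regions: int = 6, label: str = "HC",
                seed: int = 0, missing_frac: float = 0.2) -> Cohort:
    rng = np.random.default_rng(seed)
    atlas = make_atlas(n_regions, seed)
    subjects = [
        make_subject(rng, atlas, f"{label}{k:03d}", label,
                     duration=None if label == "HC" else float(rng.uniform(1, 8)),
                     missing_frac=missing_frac)
        for k in range(n_subjects)
    ]
    return Cohort(label=label, subjects=subjects, atlas=atlas)


@pytest.fixture
def small_cohort() -> Cohort:
    return make_cohort(3, 6)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
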