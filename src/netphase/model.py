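"""Core data model: parcellation atlas, subject records, cohorts, and TSV I/O.

All downstream stages operate on three containers:

``RegionAtlas``
    An ordered cortical parcellation with centroids and a boolean
    physical-adjacency matrix (region contiguity).
``SubjectRecord``
    One participant: covariates, per-region grey-matter volumes, and a
    symmetric FA-weighted connectivity matrix.  Edge weights live in
    ``(0, 1]``; edges where tractography found no streamlines are missing
    and stored as NaN.
``Cohort``
    A labelled list of subjects sharing one atlas.

On-disk dialect is tab-separated text with a header row; matrices are square
TSVs with region ids as first row/column; missing entries are the literal
``NA``.  Diagonals are never used and are written as ``NA``.
"""

from __future__ import annotations

import dataclasses
import pathlib
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

GROUPS = ("HC", "TAU", "TDP")

__all__ = [
    "GROUPS",
    "RegionAtlas",
    "SubjectRecord",
    "Cohort",
    "read_cohort",
    "write_cohort",
    "validate_inputs",
]


@dataclasses.dataclass(frozen=True)
class RegionAtlas:
    """Ordered parcellation regions with centroids and physical adjacency."""

    region_ids: tuple[str, ...]
    names: tuple[str, ...]
    hemisphere: tuple[str, ...]          # "L" or "R" per region
    centroids: np.ndarray                # (n, 3) float, mm
    adjacency: np.ndarray                # (n, n) bool, symmetric, False diagonal

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)

    def index_of(self, region_id: str) -> int:
        return self.region_ids.index(region_id)

    def centroid_distances(self) -> np.ndarray:
        """Pairwise Euclidean centroid distances, (n, n)."""
        diff = self.centroids[:, None, :] - self.centroids[None, :, :]
        return np.sqrt((diff ** 2).sum(axis=2))


@dataclasses.dataclass
class SubjectRecord:
    """Covariates, regional volumes and FA-like connectivity for one subject.

    ``connectivity`` is a square float matrix; NaN marks a missing edge and
    the diagonal is always NaN.  ``disease_duration`` is in years and may be
    None (controls).
    """

    subject_id: str
    group: str
    age: float
    icv: float
    volumes: np.ndarray
    connectivity: np.ndarray
    disease_duration: float | None = None


@dataclasses.dataclass
class Cohort:
    label: str
    subjects: list[SubjectRecord]
    atlas: RegionAtlas

    def __len__(self) -> int:
        return len(self.subjects)

    def __iter__(self):
        return iter(self.subjects)

    def volumes_matrix(self) -> np.ndarray:
        """Stack per-subject volumes, (n_subjects, n_regions)."""
        return np.vstack([s.volumes for s in self.subjects])

    def connectivity_stack(self) -> np.ndarray:
        """Stack connectivity matrices, (n_subjects, n, n)."""
        return np.stack([s.connectivity for s in self.subjects])


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_FLOAT_FMT = "%.12g"  # >= 10 significant digits for round-trip fidelity


def _fmt(x: float) -> str:
    return _FLOAT_FMT % x


def write_cohort(cohort: Cohort, out_dir: str | pathlib.Path) -> None:
    """Write a cohort plus its atlas to ``out_dir``.

    Emits ``regions.tsv``, ``adjacency.tsv``, ``covariates.tsv`` and one
    ``matrices/<subject_id>.tsv`` per subject (ordered by subject_id).
    ``read_cohort(out_dir)`` is an identity up to float formatting.
    """
    out = pathlib.Path(out_dir)
    (out / "matrices").mkdir(parents=True, exist_ok=True)
    atlas = cohort.atlas

    reg = pd.DataFrame(
        {
            "region_id": atlas.region_ids,
            "name": atlas.names,
            "hemisphere": atlas.hemisphere,
            "x": atlas.centroids[:, 0],
            "y": atlas.centroids[:, 1],
            "z": atlas.centroids[:, 2],
        }
    )
    reg.to_csv(out / "regions.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)

    adj = pd.DataFrame(
        atlas.adjacency.astype(int), index=atlas.region_ids, columns=atlas.region_ids
    )
    adj.to_csv(out / "adjacency.tsv", sep="\t", index_label="region_id")

    rows = []
    for s in sorted(cohort.subjects, key=lambda s: s.subject_id):
        rows.append(
            {
                "subject_id": s.subject_id,
                "group": s.group,
                "age": _fmt(s.age),
                "icv": _fmt(s.icv),
                "disease_duration": "NA"
                if s.disease_duration is None
                else _fmt(s.disease_duration),
            }
        )
    pd.DataFrame(rows).to_csv(out / "covariates.tsv", sep="\t", index=False)

    vol = pd.DataFrame(
        {s.subject_id: s.volumes for s in sorted(cohort.subjects, key=lambda s: s.subject_id)},
        index=atlas.region_ids,
    ).T
    vol.to_csv(out / "volumes.tsv", sep="\t", index_label="subject_id",
               float_format=_FLOAT_FMT)

    for s in sorted(cohort.subjects, key=lambda s: s.subject_id):
        m = s.connectivity.copy().astype(float)
        np.fill_diagonal(m, np.nan)
        df = pd.DataFrame(m, index=atlas.region_ids, columns=atlas.region_ids)
        df.to_csv(
            out / "matrices" / f"{s.subject_id}.tsv",
            sep="\t",
            index_label="region_id",
            na_rep="NA",
            float_format=_FLOAT_FMT,
        )


def _read_matrix(path: pathlib.Path, region_ids: Sequence[str]) -> np.ndarray:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"], keep_default_na=False)
    if list(df.index) != list(region_ids) or list(df.columns) != list(region_ids):
        raise ValueError(
            f"{path}: matrix rows/columns do not match the atlas region ids "
            f"(expected {len(region_ids)} regions)"
        )
    m = df.to_numpy(dtype=float)
    n = len(region_ids)
    if m.shape != (n, n):
        raise ValueError(f"{path}: expected a {n}x{n} matrix, got {m.shape}")
    # symmetry on defined entries, including matched missingness
    for i in range(n):
        for j in range(i + 1, n):
            a, b = m[i, j], m[j, i]
            if np.isnan(a) != np.isnan(b) or (
                not np.isnan(a) and not np.isclose(a, b, rtol=0, atol=1e-9)
            ):
                raise ValueError(
                    f"{path}: asymmetric entries at ({region_ids[i]},{region_ids[j]})="
                    f"{a} vs ({region_ids[j]},{region_ids[i]})={b}"
                )
    off = ~np.eye(n, dtype=bool)
    vals = m[off]
    bad = vals[~np.isnan(vals)]
    if bad.size and (np.any(bad <= 0) or np.any(bad > 1)):
        i, j = [(i, j) for i in range(n) for j in range(n)
                if i != j and not np.isnan(m[i, j]) and not (0 < m[i, j] <= 1)][0]
        raise ValueError(
            f"{path}: weight {m[i, j]} at ({region_ids[i]},{region_ids[j]}) "
            f"outside (0, 1]"
        )
    np.fill_diagonal(m, np.nan)
    return m


def read_cohort(in_dir: str | pathlib.Path, label: str | None = None) -> Cohort:
    """Read a cohort written by :func:`write_cohort` from ``in_dir``.

    Raises ``ValueError`` naming the offending file/cell for dimension
    mismatches, duplicate subject ids, weights outside ``(0, 1]`` and
    asymmetric matrices.
    """
    d = pathlib.Path(in_dir)
    reg = pd.read_csv(d / "regions.tsv", sep="\t", dtype={"region_id": str})
    ids = tuple(reg["region_id"])
    if len(set(ids)) != len(ids):
        raise ValueError(f"{d/'regions.tsv'}: duplicate region ids")
    adj_df = pd.read_csv(d / "adjacency.tsv", sep="\t", index_col=0)
    adjacency = adj_df.to_numpy(dtype=bool)
    atlas = RegionAtlas(
        region_ids=ids,
        names=tuple(reg["name"].astype(str)),
        hemisphere=tuple(reg["hemisphere"].astype(str)),
        centroids=reg[["x", "y", "z"]].to_numpy(dtype=float),
        adjacency=adjacency,
    )

    cov = pd.read_csv(d / "covariates.tsv", sep="\t", dtype={"subject_id": str},
                      na_values=["NA"], keep_default_na=False)
    if cov["subject_id"].duplicated().any():
        dup = cov["subject_id"][cov["subject_id"].duplicated()].iloc[0]
        raise ValueError(f"{d/'covariates.tsv'}: duplicate subject_id {dup!r}")
    vols = pd.read_csv(d / "volumes.tsv", sep="\t", index_col=0)

    subjects = []
    for _, row in cov.iterrows():
        sid = row["subject_id"]
        mpath = d / "matrices" / f"{sid}.tsv"
        if not mpath.exists():
            raise ValueError(f"missing connectivity matrix for subject {sid!r}: {mpath}")
        conn = _read_matrix(mpath, ids)
        dur = row["disease_duration"]
        subjects.append(
            SubjectRecord(
                subject_id=sid,
                group=str(row["group"]),
                age=float(row["age"]),
                icv=float(row["icv"]),
                disease_duration=None if pd.isna(dur) else float(dur),
                volumes=vols.loc[sid].to_numpy(dtype=float),
                connectivity=conn,
            )
        )
    if label is None:
        groups = {s.group for s in subjects}
        label = groups.pop() if len(groups) == 1 else "MIXED"
    return Cohort(label=label, subjects=subjects, atlas=atlas)


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def validate_inputs(cohort: Cohort, atlas: RegionAtlas | None = None) -> list[str]:
    """Return a list of human-readable invariant violations (empty iff valid)."""
    atlas = atlas or cohort.atlas
    issues: list[str] = []
    n = atlas.n_regions

    if n < 6:
        issues.append(f"atlas has {n} regions; at least 6 required")
    if len(set(atlas.region_ids)) != n:
        issues.append("atlas region_ids are not unique")
    if atlas.adjacency.shape != (n, n):
        issues.append("adjacency shape does not match region count")
    else:
        if not np.array_equal(atlas.adjacency, atlas.adjacency.T):
            issues.append("adjacency matrix is not symmetric")
        if np.any(np.diag(atlas.adjacency)):
            issues.append("adjacency diagonal must be all False")
    if not np.all(np.isfinite(atlas.centroids)):
        issues.append("atlas centroids contain non-finite values")

    if not cohort.subjects:
        issues.append("cohort is empty")
    seen: set[str] = set()
    for s in cohort.subjects:
        tag = f"subject {s.subject_id!r}"
        if s.subject_id in seen:
            issues.append(f"{tag}: duplicate subject_id")
        seen.add(s.subject_id)
        if s.group != cohort.label:
            issues.append(f"{tag}: group {s.group!r} does not match cohort label "
                          f"{cohort.label!r}")
        if not s.age > 0:
            issues.append(f"{tag}: non-positive age {s.age}")
        if not s.icv > 0:
            issues.append(f"{tag}: non-positive intracranial volume {s.icv}")
        if s.volumes.shape != (n,):
            issues.append(f"{tag}: volumes length {s.volumes.shape} != {n}")
        elif np.any(~(s.volumes > 0)):
            r = int(np.argmin(s.volumes > 0))
            issues.append(f"{tag}: non-positive volume in region "
                          f"{atlas.region_ids[r]}")
        c = s.connectivity
        if c.shape != (n, n):
            issues.append(f"{tag}: connectivity shape {c.shape} != ({n}, {n})")
            continue
        for i in range(n):
            for j in range(i + 1, n):
                if np.isnan(c[i, j]) != np.isnan(c[j, i]) or (
                    not np.isnan(c[i, j]) and c[i, j] != c[j, i]
                ):
                    issues.append(
                        f"{tag}: asymmetric connectivity at "
                        f"({atlas.region_ids[i]},{atlas.region_ids[j]})"
                    )
        off = c[~np.eye(n, dtype=bool)]
        vals = off[~np.isnan(off)]
        if vals.size and (vals.min() <= 0 or vals.max() > 1):
            issues.append(f"{tag}: connectivity weights outside (0, 1]")
    return issues
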