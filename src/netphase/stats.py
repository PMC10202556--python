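"""Statistical harness and the imaging-histopathology association stage.

Group comparisons use Welch's t-test (reported with both the fractional
Satterthwaite df and the pooled integer df n1 + n2 - 2, since published
captions conventionally print the latter), Mann-Whitney U (asymptotic,
tie-corrected), Pearson chi-square without continuity correction, and
one-way ANOVA.  Regressions report the least-squares slope with its t-test
and Pearson's r with its exact t-transform p-value.  All tests are
two-sided; no multiple-comparison correction by default.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy import stats as sps

from .edges import node_mean_edge_z
from .model import Cohort

logger = logging.getLogger(__name__)

__all__ = [
    "TestResult",
    "RegressionResult",
    "welch_t",
    "anova_oneway",
    "mann_whitney_u",
    "chi_square",
    "linreg_pearson",
    "histo_association",
]


@dataclasses.dataclass
class TestResult:
    name: str
    statistic: float
    p_value: float
    df: float | tuple[float, float] | None = None     # Welch/ANOVA df
    df_pooled: int | None = None                      # n1 + n2 - 2
    group_means: tuple[float, ...] | None = None
    n: tuple[int, ...] | None = None


@dataclasses.dataclass
class RegressionResult:
    slope: float
    intercept: float
    slope_p: float
    r: float
    r_p: float
    n: int


def welch_t(x, y) -> TestResult:
    """Welch's two-sample t-test (unequal variances), two-sided."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    if x.std(ddof=1) == 0 and y.std(ddof=1) == 0:
        raise ValueError("zero variance in both groups; t undefined")
    res = sps.ttest_ind(x, y, equal_var=False)
    return TestResult(
        name="welch_t",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        df=float(res.df),
        df_pooled=int(x.size + y.size - 2),
        group_means=(float(x.mean()), float(y.mean())),
        n=(int(x.size), int(y.size)),
    )


def anova_oneway(groups) -> TestResult:
    """One-way ANOVA; F with df (k - 1, N - k)."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    if all(np.ptp(g) == 0 for g in groups) and len({g[0] for g in groups}) == 1:
        raise ValueError("all observations identical; F undefined")
    res = sps.f_oneway(*groups)
    k = len(groups)
    n_total = sum(g.size for g in groups)
    return TestResult(
        name="anova_oneway",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        df=(float(k - 1), float(n_total - k)),
        group_means=tuple(float(g.mean()) for g in groups),
        n=tuple(int(g.size) for g in groups),
    )


def mann_whitney_u(x, y) -> TestResult:
    """Mann-Whitney U, asymptotic normal approximation with tie correction."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("empty sample")
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        return TestResult(name="mann_whitney_u", statistic=x.size * y.size / 2.0,
                          p_value=1.0, n=(int(x.size), int(y.size)))
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic",
                           use_continuity=False)
    return TestResult(name="mann_whitney_u", statistic=float(res.statistic),
                      p_value=float(res.pvalue),
                      n=(int(x.size), int(y.size)))


def chi_square(table) -> TestResult:
    """Pearson chi-square on an r x c contingency table, (r-1)(c-1) df."""
    table = np.asarray(table, dtype=float)
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("contingency table has a zero margin")
    stat, p, df, _ = sps.chi2_contingency(table, correction=False)
    return TestResult(name="chi_square", statistic=float(stat),
                      p_value=float(p), df=float(df))


def linreg_pearson(x, y) -> RegressionResult:
    """Least-squares slope with t-test; Pearson r with t-transform p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired finite observations")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in x; slope undefined")
    fit = sps.linregress(x, y)
    r, r_p = sps.pearsonr(x, y)
    return RegressionResult(slope=float(fit.slope), intercept=float(fit.intercept),
                            slope_p=float(fit.pvalue), r=float(r), r_p=float(r_p),
                            n=int(x.size))


def histo_association(cohort: Cohort, zmatrices: dict[str, np.ndarray],
                      histo_table: pd.DataFrame, max_duration: float = 5.0
                      ) -> dict[str, RegressionResult | None]:
    """Regress %AO on the node mean edge z, per tissue, short-duration subjects.

    Keeps subjects with disease_duration <= max_duration; pairs each sampled
    (subject, region, tissue) %AO with that subject's mean z over the edges
    incident to the region; fits a regression per tissue (GM, WM).  Returns
    None for a tissue with fewer than 3 usable pairs.
    """
    region_index = {rid: i for i, rid in enumerate(cohort.atlas.region_ids)}
    keep = {
        s.subject_id
        for s in cohort.subjects
        if s.disease_duration is not None and s.disease_duration <= max_duration
    }
    out: dict[str, RegressionResult | None] = {}
    for tissue in ("GM", "WM"):
        xs, ys = [], []
        sub = histo_table[(histo_table["tissue"] == tissue)
                          & histo_table["subject_id"].isin(keep)]
        for _, row in sub.iterrows():
            z = zmatrices.get(row["subject_id"])
            if z is None:
                continue
            mz = node_mean_edge_z(z, region_index[row["region_id"]])
            if mz is None:
                continue
            xs.append(mz)
            ys.append(float(row["pct_area_occupied"]))
        if len(xs) < 3:
            logger.warning("histology association (%s): only %d usable pairs; "
                           "skipped", tissue, len(xs))
            out[tissue] = None
        else:
            out[tissue] = linreg_pearson(np.array(xs), np.array(ys))
    return out
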