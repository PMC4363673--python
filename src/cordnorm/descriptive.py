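"""Descriptive statistics: Pearson correlation tables, normality, %RSD, pooled moments.

Conventions used throughout: sample standard deviations with the n−1
denominator, two-sided p-values, pairwise (not listwise) deletion for
correlation tables with the per-cell complete-case n always reported, and no
multiple-comparison correction (these are exploratory tables).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["pearson", "CorrelationTable", "correlation_table",
           "shapiro_wilk", "rsd", "pooled_moments"]


def _complete_pairs(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    ok = ~(np.isnan(x) | np.isnan(y))
    return x[ok], y[ok]


def pearson(x, y) -> tuple[float, float, int]:
    """Pearson product-moment correlation with a two-sided p-value.

    Pairwise deletion of incomplete pairs; the p-value comes from the
    t transform ``t = r·sqrt((n−2)/(1−r²))`` on n−2 df.

    Returns
    -------
    (r, p, n) : coefficient, two-sided p, number of complete pairs used.
    """
    xv, yv = _complete_pairs(x, y)
    n = len(xv)
    if n < 3:
        raise ValueError(f"need at least 3 complete pairs, got {n}")
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        raise ValueError("zero variance in one of the series")
    res = sps.pearsonr(xv, yv)
    return float(res.statistic), float(res.pvalue), n


@dataclass
class CorrelationTable:
    """Cell-wise Pearson correlations between two variable lists.

    Attributes
    ----------
    r, p, n : DataFrames indexed by ``row_vars`` × ``col_vars`` holding the
        coefficient, two-sided p and complete-case count per cell.
    """

    r: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame

    @property
    def row_vars(self) -> list[str]:
        return list(self.r.index)

    @property
    def col_vars(self) -> list[str]:
        return list(self.r.columns)

    def cell(self, row: str, col: str) -> tuple[float, float, int]:
        return (float(self.r.loc[row, col]), float(self.p.loc[row, col]),
                int(self.n.loc[row, col]))


def correlation_table(data: pd.DataFrame, row_vars, col_vars) -> CorrelationTable:
    """Pearson correlations of ``row_vars`` against ``col_vars``.

    ``data`` is any one-row-per-subject frame (e.g.
    :meth:`cordnorm.cohort.Cohort.analysis_frame`).  Pairwise deletion per
    cell; identical row/column variable yields r = 1 exactly.
    """
    row_vars = list(row_vars)
    col_vars = list(col_vars)
    for v in row_vars + col_vars:
        if v not in data.columns:
            raise KeyError(f"unknown variable {v!r}")
    r = pd.DataFrame(index=row_vars, columns=col_vars, dtype=float)
    p = pd.DataFrame(index=row_vars, columns=col_vars, dtype=float)
    n = pd.DataFrame(index=row_vars, columns=col_vars, dtype=int)
    for a in row_vars:
        for b in col_vars:
            if a == b:
                xv, yv = _complete_pairs(data[a], data[b])
                r.loc[a, b], p.loc[a, b], n.loc[a, b] = 1.0, 0.0, len(xv)
            else:
                ri, pi, ni = pearson(data[a], data[b])
                r.loc[a, b], p.loc[a, b], n.loc[a, b] = ri, pi, ni
    return CorrelationTable(r=r, p=p, n=n)


def shapiro_wilk(values) -> tuple[float, float]:
    """Shapiro–Wilk W test of normality (delegates to scipy).

    Valid for 3 ≤ n ≤ 5000 after dropping missing values; constant input is
    an error.
    """
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if not 3 <= len(v) <= 5000:
        raise ValueError(f"Shapiro-Wilk needs 3 <= n <= 5000, got {len(v)}")
    if np.ptp(v) == 0:
        raise ValueError("constant input")
    w, p = sps.shapiro(v)
    return float(w), float(p)


def rsd(values) -> float:
    """Relative standard deviation, 100 × sample SD (n−1) / mean, in percent."""
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if len(v) < 2:
        raise ValueError("need at least 2 values")
    m = v.mean()
    if m == 0:
        raise ValueError("mean is zero")
    return float(100.0 * v.std(ddof=1) / m)


def pooled_moments(groups) -> tuple[int, float, float]:
    """Exact pooled (n, mean, SD) from per-group ``(n, mean, sd)`` triples.

    Uses the total sum-of-squares decomposition (within + between) with the
    n−1 denominator, so the result equals the direct computation on the
    concatenated raw data.
    """
    groups = list(groups)
    if not groups:
        raise ValueError("empty group list")
    for n_i, _, _ in groups:
        if n_i < 2:
            raise ValueError("each group needs n >= 2")
    ntot = sum(n for n, _, _ in groups)
    mean = sum(n * m for n, m, _ in groups) / ntot
    ss_within = sum((n - 1) * s ** 2 for n, _, s in groups)
    ss_between = sum(n * (m - mean) ** 2 for n, m, _ in groups)
    sd = float(np.sqrt((ss_within + ss_between) / (ntot - 1)))
    return int(ntot), float(mean), sd
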