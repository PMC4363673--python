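"""Covariate-adjusted two-group comparisons (least-square means).

`AdjustedMeans` follows the statsmodels Model/Results convention: construct
from a one-row-per-subject DataFrame (or a :class:`~cordnorm.cohort.Cohort`),
call :meth:`~AdjustedMeans.fit`, and read estimates off the returned
:class:`AdjustedMeansResults`.

The adjusted mean of a group is the fitted-model prediction for that group
with every covariate held at its grand (complete-case) mean — the standard
least-square-means convention, matching a single adjustment shared by both
groups (equal-slopes model, no group×covariate interaction).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .cohort import Cohort, column_for

__all__ = ["AdjustedMeans", "AdjustedMeansResults", "ls_means",
           "median_split", "covariate_screen"]


class AdjustedMeans:
    """Linear model ``outcome ~ group + covariates`` for two-group comparison.

    Parameters
    ----------
    data : one row per subject; must contain `outcome`, `factor` and the
        covariate columns.  Incomplete rows are dropped (complete-case).
    outcome : outcome column name.
    factor : grouping column with exactly two observed levels.
    covariates : covariate column names entering the adjustment.
    levels : optional (first, second) order; the difference is
        first − second.  Defaults to sorted descending so that ``sex``
        yields M − F.
    """

    def __init__(self, data: pd.DataFrame, outcome: str, factor: str,
                 covariates=(), levels: tuple | None = None):
        cols = [outcome, factor, *covariates]
        missing = [c for c in cols if c not in data.columns]
        if missing:
            raise KeyError(f"missing column(s) {missing}")
        frame = data[cols].dropna().reset_index(drop=True)
        observed = pd.unique(frame[factor])
        if len(observed) != 2:
            raise ValueError(
                f"factor {factor!r} must have exactly 2 observed levels, "
                f"got {list(observed)}")
        if levels is None:
            levels = tuple(sorted(observed, reverse=True))
        elif set(levels) != set(observed):
            raise ValueError(f"levels {levels} do not match observed "
                             f"{list(observed)}")
        if len(frame) < len(covariates) + 3:
            raise ValueError(
                f"too few complete cases (n={len(frame)}) for "
                f"{len(covariates)} covariates")
        self.data = frame
        self.outcome = outcome
        self.factor = factor
        self.covariates = tuple(covariates)
        self.levels = levels

    @classmethod
    def from_cohort(cls, cohort: Cohort, level: str, measure: str,
                    factor: str, covariates=(), levels=None) -> "AdjustedMeans":
        """Build from a cohort for one (disc level, cord measure) outcome.

        ``factor`` may be any subjects column (e.g. ``sex``) or a column of
        the analysis frame (e.g. a previously attached age-group label).
        """
        frame = cohort.analysis_frame()
        return cls(frame, column_for(level, measure), factor, covariates,
                   levels=levels)

    def fit(self) -> "AdjustedMeansResults":
        frame = self.data
        first, second = self.levels
        indicator = (frame[self.factor] == first).to_numpy(dtype=float)
        X = np.column_stack([np.ones(len(frame)), indicator]
                            + [frame[c].to_numpy(dtype=float)
                               for c in self.covariates])
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("rank-deficient design matrix")
        y = frame[self.outcome].to_numpy(dtype=float)
        res = sm.OLS(y, X).fit()
        V = res.cov_params()
        zbar = [frame[c].mean() for c in self.covariates]
        adjusted, se = {}, {}
        for lev, ind in ((first, 1.0), (second, 0.0)):
            x = np.array([1.0, ind, *zbar])
            adjusted[lev] = float(x @ res.params)
            se[lev] = float(np.sqrt(x @ V @ x))
        diff = float(res.params[1])
        se_diff = float(res.bse[1])
        df = int(res.df_resid)
        p = float(res.pvalues[1])
        tq = sps.t.ppf(0.975, df)
        return AdjustedMeansResults(
            outcome=self.outcome, factor=self.factor, levels=self.levels,
            adjusted_means=adjusted, se_means=se, difference=diff,
            se_difference=se_diff, pvalue=p,
            conf_int=(diff - tq * se_diff, diff + tq * se_diff),
            covariates=self.covariates, n=len(frame), df_resid=df)


@dataclass
class AdjustedMeansResults:
    """Covariate-adjusted comparison of one outcome between two groups."""

    outcome: str
    factor: str
    levels: tuple
    adjusted_means: dict
    se_means: dict
    difference: float          # first level − second level
    se_difference: float
    pvalue: float              # two-sided t on residual df
    conf_int: tuple[float, float]
    covariates: tuple
    n: int
    df_resid: int

    def summary(self) -> pd.DataFrame:
        first, second = self.levels
        rows = [
            {"group": first, "adj_mean": self.adjusted_means[first],
             "se_mean": self.se_means[first]},
            {"group": second, "adj_mean": self.adjusted_means[second],
             "se_mean": self.se_means[second]},
        ]
        out = pd.DataFrame(rows)
        out["difference"] = [self.difference, np.nan]
        out["se_difference"] = [self.se_difference, np.nan]
        out["p"] = [self.pvalue, np.nan]
        out["ci_low"] = [self.conf_int[0], np.nan]
        out["ci_high"] = [self.conf_int[1], np.nan]
        out["n"] = [self.n, np.nan]
        return out


def ls_means(data, outcome: str, factor: str, covariates=(),
             levels=None) -> AdjustedMeansResults:
    """Least-square-means comparison; thin wrapper over :class:`AdjustedMeans`.

    ``data`` may be a DataFrame or a Cohort (then ``outcome`` is
    ``"LEVEL:measure"``, e.g. ``"C2-C3:tca"``).
    """
    if isinstance(data, Cohort):
        level, measure = outcome.split(":")
        return AdjustedMeans.from_cohort(data, level, measure, factor,
                                         covariates, levels=levels).fit()
    return AdjustedMeans(data, outcome, factor, covariates,
                         levels=levels).fit()


def median_split(values, label: str = "") -> tuple[pd.Series, float]:
    """Split at the sample median; ties at the cutoff go to the upper group.

    Returns (labels, cutoff) where labels are ``"< c"`` / ``">= c"``.
    """
    v = pd.Series(values).astype(float)
    obs = v.dropna()
    if obs.nunique() < 2:
        raise ValueError("all values identical; cannot median-split")
    cutoff = float(obs.median())
    lo, hi = f"< {cutoff:g}", f">= {cutoff:g}"
    labels = pd.Series(np.where(v >= cutoff, hi, lo), index=v.index,
                       name=label or "group")
    labels[v.isna()] = None
    return labels, cutoff


def covariate_screen(data, outcome: str,
                     covariates=("age", "sex_male", "height", "weight"),
                     alpha_flag: float = 0.1,
                     bonferroni: bool = False) -> pd.DataFrame:
    """Multiple linear regression screen of demographic covariates.

    One OLS fit of ``outcome`` on all covariates jointly (complete cases);
    per-covariate two-sided p-values, optionally Bonferroni-corrected,
    and a flag for p < ``alpha_flag``.
    """
    if isinstance(data, Cohort):
        data = data.analysis_frame()
    cols = [outcome, *covariates]
    frame = data[cols].dropna()
    if len(frame) < len(covariates) + 3:
        raise ValueError("too few complete cases")
    X = sm.add_constant(frame[list(covariates)].to_numpy(dtype=float))
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design matrix")
    res = sm.OLS(frame[outcome].to_numpy(dtype=float), X).fit()
    p = res.pvalues[1:]
    if bonferroni:
        p = np.minimum(p * len(covariates), 1.0)
    return pd.DataFrame({
        "covariate": list(covariates),
        "coefficient": res.params[1:],
        "se": res.bse[1:],
        "p": p,
        "flagged": p < alpha_flag,
        "n": len(frame),
    })
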