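"""Regression-based residual normalization of spinal cord areas.

The residual method replaces a measured area with its value adjusted to the
cohort-mean covariates through fitted regression coefficients:

    A_pred = A_meas + a·(X̄ − X) + b·(Ȳ − Y) + c·(Z̄ − Z) + …

where a, b, c, … are the coefficients of a multi-linear OLS fit of the area
on the covariates and X̄, Ȳ, Z̄, … are the covariate means of the fitting
cohort (frozen into the model, so the same reference means are reused when
normalizing new subjects).  Applied in-sample this is exactly
"measurement minus fitted systematic part plus grand mean", hence it
preserves the outcome mean and satisfies

    %RSD_norm = %RSD_meas · √(1 − R²)

with the unadjusted in-sample R².

Workflow pieces mirror the published analysis: Pearson screening of
skull/vertebra candidate covariates (r > 0.45 with TCA or GM at the
reference level), OLS model fitting with an adjusted-R² > 0.35 retention
gate, %RSD evaluation, and transfer of the selected covariate set to other
disc levels (coefficients are refitted per level).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
import yaml

from .cohort import Cohort, column_for
from .descriptive import CorrelationTable, rsd

__all__ = ["ResidualNormalizer", "NormalizationResults", "RSDEvaluation",
           "screen_predictors", "fit_model", "apply_normalization",
           "evaluate_model", "transfer_model", "load_reference_models",
           "SKULL_VERTEBRA_METRICS", "ADJ_R2_GATE", "SCREEN_THRESHOLD"]

#: head-size covariates considered robust to neurological disease: skull and
#: vertebra derived metrics (brain tissue volumes are excluded by design)
SKULL_VERTEBRA_METRICS = (
    "ticv", "nasion_inion", "foramen_magnum_area", "mcrae_line",
    "mcraes_to_c4", "ap_canal_diameter", "ap_vertebra_diameter",
    "middle_vertebra_height", "mean_vertebra_height",
    "sagittal_vertebra_area", "sagittal_area_trapez",
)

ADJ_R2_GATE = 0.35
SCREEN_THRESHOLD = 0.45


def screen_predictors(corr: CorrelationTable, threshold: float = SCREEN_THRESHOLD,
                      candidates=SKULL_VERTEBRA_METRICS) -> list[str]:
    """Candidate covariates correlating with TCA or GM above the threshold.

    ``corr`` must have one row for TCA and one for GM at the reference level
    (row labels containing ``"tca"`` / ``"gm"``, e.g. from
    :func:`cordnorm.descriptive.correlation_table` on the analysis frame).
    Retention is strict: r > threshold with at least one of the two cord
    measures; r exactly at the threshold is excluded.  Only columns in
    ``candidates`` are considered.
    """
    rows = [r for r in corr.row_vars
            if r.lower().startswith(("tca", "gm"))]
    has_tca = any(r.lower().startswith("tca") for r in rows)
    has_gm = any(r.lower().startswith("gm") for r in rows)
    if not (has_tca and has_gm):
        raise ValueError("correlation table needs both a TCA and a GM row")
    kept = []
    for col in corr.col_vars:
        if col not in candidates:
            continue
        if any(float(corr.r.loc[row, col]) > threshold for row in rows):
            kept.append(col)
    return kept


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

class ResidualNormalizer:
    """OLS normalization model for one (disc level, cord measure) outcome.

    Parameters
    ----------
    data : one-row-per-subject DataFrame containing the outcome and
        covariate columns (incomplete rows dropped).
    outcome : outcome column name, or ``"LEVEL:measure"`` when constructed
        through :meth:`from_cohort`.
    covariates : covariate column names (order is kept).
    """

    def __init__(self, data: pd.DataFrame, outcome: str, covariates):
        covariates = list(covariates)
        missing = [c for c in [outcome, *covariates] if c not in data.columns]
        if missing:
            raise KeyError(f"missing column(s) {missing}")
        frame = data[[outcome, *covariates]].dropna().reset_index(drop=True)
        if len(frame) < len(covariates) + 3:
            raise ValueError(
                f"too few complete cases (n={len(frame)}) for "
                f"p={len(covariates)} covariates")
        self.data = frame
        self.outcome = outcome
        self.covariates = covariates

    @classmethod
    def from_cohort(cls, cohort: Cohort, level: str, measure: str,
                    covariates) -> "ResidualNormalizer":
        frame = cohort.analysis_frame()
        model = cls(frame, column_for(level, measure), covariates)
        model.outcome_label = f"{level}:{measure.lower()}"
        return model

    def fit(self) -> "NormalizationResults":
        y = self.data[self.outcome].to_numpy(dtype=float)
        Xc = self.data[self.covariates].to_numpy(dtype=float)
        X = sm.add_constant(Xc)
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("rank-deficient design matrix")
        res = sm.OLS(y, X).fit()
        means = {c: float(self.data[c].mean()) for c in self.covariates}
        return NormalizationResults(
            outcome=getattr(self, "outcome_label", self.outcome),
            outcome_column=self.outcome,
            covariates=list(self.covariates),
            coefficients={c: float(b) for c, b
                          in zip(self.covariates, res.params[1:])},
            coefficient_pvalues={c: float(p) for c, p
                                 in zip(self.covariates, res.pvalues[1:])},
            covariate_means=means,
            intercept=float(res.params[0]),
            r2=float(res.rsquared),
            adj_r2=float(res.rsquared_adj),
            n=len(self.data),
            outcome_mean=float(y.mean()),
        )


@dataclass
class NormalizationResults:
    """Fitted residual-normalization model.

    Carries one coefficient and one frozen covariate mean per covariate,
    the fit statistics, and the adjusted-R² retention gate.  The covariate
    means default to the fitting sample's; supply ``reference_means`` when
    applying published models to a new cohort.
    """

    outcome: str
    outcome_column: str
    covariates: list[str]
    coefficients: dict[str, float]
    coefficient_pvalues: dict[str, float]
    covariate_means: dict[str, float]
    intercept: float
    r2: float
    adj_r2: float
    n: int
    outcome_mean: float
    #: fitting sample, set by :func:`fit_model` for in-sample evaluation
    fitting_frame: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def passes_gate(self) -> bool:
        """Adjusted R² strictly above the retention gate (0.35)."""
        return self.adj_r2 > ADJ_R2_GATE

    # -- Eq.-style application --------------------------------------------
    def apply(self, a_meas: float, covariate_values: dict[str, float],
              reference_means: dict[str, float] | None = None) -> float:
        """Normalize one measurement: A_pred = A_meas + Σ coef·(mean − value).

        ``covariate_values`` must supply exactly the model covariates
        (no extras, no omissions).  Pure arithmetic; no refitting.
        """
        means = self.covariate_means if reference_means is None else reference_means
        extra = set(covariate_values) - set(self.covariates)
        absent = set(self.covariates) - set(covariate_values)
        if extra or absent:
            raise ValueError(
                f"covariate mismatch: extras {sorted(extra)}, "
                f"missing {sorted(absent)}")
        out = float(a_meas)
        for c in self.covariates:
            v = covariate_values[c]
            if v is None or (isinstance(v, float) and np.isnan(v)):
                raise ValueError(f"missing value for covariate {c!r}")
            out += self.coefficients[c] * (means[c] - float(v))
        return out

    def normalize(self, data: pd.DataFrame | None = None,
                  reference_means: dict[str, float] | None = None) -> pd.Series:
        """Normalized values for a frame (default: the fitting sample)."""
        frame = self.fitting_frame if data is None else data
        if frame is None:
            raise ValueError("no data: model was not fitted in this session")
        means = self.covariate_means if reference_means is None else reference_means
        out = frame[self.outcome_column].astype(float).copy()
        for c in self.covariates:
            out = out + self.coefficients[c] * (means[c] - frame[c].astype(float))
        return out.rename(f"{self.outcome_column}_normalized")

    def evaluate(self, data: pd.DataFrame | None = None,
                 reference_means: dict[str, float] | None = None
                 ) -> "RSDEvaluation":
        """%RSD of measured vs normalized values and the relative reduction."""
        frame = self.fitting_frame if data is None else data
        if frame is None:
            raise ValueError("no data: model was not fitted in this session")
        frame = frame[[self.outcome_column, *self.covariates]].dropna()
        meas = rsd(frame[self.outcome_column])
        norm = rsd(self.normalize(frame, reference_means=reference_means))
        return RSDEvaluation(rsd_meas=meas, rsd_norm=norm,
                             reduction=100.0 * (1.0 - norm / meas),
                             n=len(frame))

    def summary(self) -> str:
        lines = [f"Residual normalization model: {self.outcome}",
                 f"  n = {self.n}, R² = {self.r2:.3f}, "
                 f"adj. R² = {self.adj_r2:.3f} "
                 f"({'passes' if self.passes_gate else 'fails'} the "
                 f"adj. R² > {ADJ_R2_GATE} gate)"]
        for c in self.covariates:
            lines.append(f"  {c:28s} coef = {self.coefficients[c]:12.6g}  "
                         f"mean = {self.covariate_means[c]:12.6g}  "
                         f"p = {self.coefficient_pvalues[c]:.4f}")
        return "\n".join(lines)

    # -- persistence --------------------------------------------------------
    def to_dict(self) -> dict:
        return {"outcome": self.outcome,
                "outcome_column": self.outcome_column,
                "covariates": list(self.covariates),
                "coefficients": dict(self.coefficients),
                "coefficient_pvalues": dict(self.coefficient_pvalues),
                "covariate_means": dict(self.covariate_means),
                "intercept": self.intercept, "r2": self.r2,
                "adj_r2": self.adj_r2, "n": self.n,
                "outcome_mean": self.outcome_mean}

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict) -> "NormalizationResults":
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "NormalizationResults":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class RSDEvaluation:
    rsd_meas: float     # %RSD of the measured values
    rsd_norm: float     # %RSD after normalization
    reduction: float    # relative reduction, percent of the measured %RSD
    n: int


# ---------------------------------------------------------------------------
# functional wrappers
# ---------------------------------------------------------------------------

def fit_model(cohort, outcome: str, covariates) -> NormalizationResults:
    """Fit a normalization model; ``outcome`` is ``"LEVEL:measure"`` for a
    Cohort or a column name for a DataFrame."""
    if isinstance(cohort, Cohort):
        level, measure = outcome.split(":")
        model = ResidualNormalizer.from_cohort(cohort, level, measure,
                                               covariates)
    else:
        model = ResidualNormalizer(cohort, outcome, covariates)
    res = model.fit()
    res.fitting_frame = model.data
    return res


def apply_normalization(model: NormalizationResults, a_meas: float,
                        covariate_values: dict[str, float],
                        reference_means: dict[str, float] | None = None
                        ) -> float:
    return model.apply(a_meas, covariate_values,
                       reference_means=reference_means)


def evaluate_model(model: NormalizationResults, cohort=None) -> RSDEvaluation:
    if isinstance(cohort, Cohort):
        cohort = cohort.analysis_frame()
    return model.evaluate(cohort)


def transfer_model(covariates, target_level: str, cohort,
                   measure: str = "tca", drop_candidates=None,
                   alpha: float = 0.05
                   ) -> tuple[NormalizationResults, RSDEvaluation]:
    """Refit a reference-level covariate set on another disc level.

    Coefficients are level-specific, so the model is refitted on the target
    level's outcome.  Mirroring the published workflow, dropping a covariate
    is data-driven but restricted: only age is ever a drop candidate, and
    only for gray-matter outcomes (where the published models shed it once
    its coefficient stopped being significant); it is removed and the model
    refitted when its two-sided coefficient p ≥ ``alpha``.  TCA transfers
    keep the full covariate set.  Pass ``drop_candidates`` explicitly to
    override.
    """
    if drop_candidates is None:
        drop_candidates = ("age",) if measure.lower() == "gm" else ()
    outcome = f"{target_level}:{measure}"
    res = fit_model(cohort, outcome, list(covariates))
    dropped = [c for c in res.covariates
               if c in drop_candidates and res.coefficient_pvalues[c] >= alpha]
    if dropped:
        res = fit_model(cohort, outcome,
                        [c for c in res.covariates if c not in dropped])
    return res, res.evaluate()


# ---------------------------------------------------------------------------
# packaged reference models
# ---------------------------------------------------------------------------

def load_reference_models() -> dict[str, NormalizationResults]:
    """Published reference normalization models (healthy-adult calibration).

    Coefficients and cohort covariate means as published for the 32-subject
    reference cohort; apply them to new data with
    ``model.apply(..., )`` / ``model.normalize(df)`` — the frozen reference
    means are used, no refitting.  R²/p-value slots that the publication
    does not report are NaN.
    """
    text = (resources.files("cordnorm") / "data" / "reference_models.yaml"
            ).read_text(encoding="utf-8")
    raw = yaml.safe_load(text)
    out = {}
    for key, entry in raw["models"].items():
        covs = list(entry["coefficients"])
        out[key] = NormalizationResults(
            outcome=entry["outcome"],
            outcome_column=column_for(*entry["outcome"].split(":")),
            covariates=covs,
            coefficients={c: float(v) for c, v in entry["coefficients"].items()},
            coefficient_pvalues={c: float("nan") for c in covs},
            covariate_means={c: float(raw["covariate_means"][c]) for c in covs},
            intercept=float("nan"),
            r2=float("nan"),
            adj_r2=float(entry.get("adj_r2", float("nan"))
                         if entry.get("adj_r2") is not None else float("nan")),
            n=int(raw["n"]),
            outcome_mean=float("nan"),
        )
    return out
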