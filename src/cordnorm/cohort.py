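"""Cohort container: subjects, per-level cord areas, and head/vertebra covariates.

A :class:`Cohort` is a thin, validated bundle of three tables
(pandas DataFrames) mirroring the three CSV files of the on-disk layout:

* ``subjects.csv``   — ``id, sex, age, height, weight``
* ``cord.csv``       — ``id, level, tca_mm2, gm_mm2`` (+ derived columns)
* ``covariates.csv`` — ``id`` + one column per brain/skull/vertebra metric

Units are fixed: areas mm², volumes mm³, lengths mm, age years.  Missing data
are represented by absent rows or empty cells (NaN), never by zeros.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

#: canonical disc-level labels, cranial to caudal
LEVELS = ("C2-C3", "C3-C4", "T8-T9", "T9-T10")
CERVICAL_LEVELS = ("C2-C3", "C3-C4")
THORACIC_LEVELS = ("T8-T9", "T9-T10")

SEXES = ("M", "F")

#: covariate columns accepted in covariates.csv (all optional per subject)
MEASURED_COVARIATES = (
    "ticv",
    "total_cortex",
    "subcortical_gm",
    "total_gm",
    "total_wm",
    "brain",
    "precentral_gm",
    "thalamus",
    "cerebellum",
    "brainstem",
    "foramen_magnum_area",
    "nasion_inion",
    "mcrae_line",
    "mcraes_to_c4",
    "ap_canal_diameter",
    "ap_vertebra_diameter",
    "middle_vertebra_height",
    "anterior_height",
    "posterior_height",
)
DERIVED_COVARIATES = (
    "mean_vertebra_height",
    "sagittal_vertebra_area",
    "sagittal_area_trapez",
)
COVARIATE_COLUMNS = MEASURED_COVARIATES + DERIVED_COVARIATES

SUBJECT_COLUMNS = ("id", "sex", "age", "height", "weight")
CORD_RAW_COLUMNS = ("id", "level", "tca_mm2", "gm_mm2")
CORD_DERIVED_COLUMNS = ("wm_mm2", "gm_fraction")


class CohortError(ValueError):
    """Schema or invariant violation in cohort data."""


@dataclass
class Cohort:
    """Demographics, cord areas and covariates for one study cohort.

    Parameters
    ----------
    subjects : DataFrame with columns ``id, sex, age, height, weight``.
    cord : DataFrame with columns ``id, level, tca_mm2, gm_mm2`` and, after
        :func:`derive_metrics`, ``wm_mm2`` and ``gm_fraction``.
    covariates : DataFrame with an ``id`` column plus any subset of
        :data:`COVARIATE_COLUMNS`.
    age_range : plausibility bounds for age (years), validated on construction.
    """

    subjects: pd.DataFrame
    cord: pd.DataFrame
    covariates: pd.DataFrame
    age_range: tuple[float, float] = (18.0, 100.0)

    def __post_init__(self) -> None:
        self.subjects = self.subjects.reset_index(drop=True)
        self.cord = self.cord.reset_index(drop=True)
        self.covariates = self.covariates.reset_index(drop=True)
        validate_cohort(self)

    # -- convenience -------------------------------------------------------
    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    def level_table(self, level: str, measure: str = "tca") -> pd.Series:
        """Values of one cord measure at one level, indexed by subject id."""
        if level not in LEVELS:
            raise CohortError(f"unknown level {level!r}")
        col = {"tca": "tca_mm2", "gm": "gm_mm2", "wm": "wm_mm2",
               "gm_fraction": "gm_fraction"}.get(measure.lower())
        if col is None:
            raise CohortError(f"unknown cord measure {measure!r}")
        sub = self.cord[self.cord["level"] == level]
        return sub.set_index("id")[col]

    def analysis_frame(self) -> pd.DataFrame:
        """One row per subject: demographics, covariates and wide cord areas.

        Cord areas appear as ``tca_<level>`` / ``gm_<level>`` / ``wm_<level>``
        columns (hyphens dropped, lowercase, e.g. ``tca_c2c3``).  Missing
        records become NaN so downstream analyses can do their own
        complete-case filtering.
        """
        out = self.subjects.set_index("id").copy()
        if len(self.covariates):
            out = out.join(self.covariates.set_index("id"), how="left")
        else:
            for c in COVARIATE_COLUMNS:
                out[c] = np.nan
        for level in LEVELS:
            tag = level.replace("-", "").lower()
            sub = self.cord[self.cord["level"] == level].set_index("id")
            for meas, col in (("tca", "tca_mm2"), ("gm", "gm_mm2"),
                              ("wm", "wm_mm2"), ("gmfrac", "gm_fraction")):
                if col in sub.columns:
                    out[f"{meas}_{tag}"] = sub[col]
                else:
                    out[f"{meas}_{tag}"] = np.nan
        out["sex_male"] = (out["sex"] == "M").astype(float)
        return out.reset_index()


def column_for(level: str, measure: str) -> str:
    """Wide-format column name used by :meth:`Cohort.analysis_frame`."""
    return f"{measure.lower()}_{level.replace('-', '').lower()}"


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def validate_cohort(cohort: Cohort) -> None:
    subj = cohort.subjects
    for col in SUBJECT_COLUMNS:
        if col not in subj.columns:
            raise CohortError(f"subjects table missing column {col!r}")
    if subj["id"].duplicated().any():
        dup = subj.loc[subj["id"].duplicated(), "id"].iloc[0]
        raise CohortError(f"duplicate subject id {dup!r}")
    bad_sex = ~subj["sex"].isin(SEXES)
    if bad_sex.any():
        row = int(np.flatnonzero(bad_sex)[0])
        raise CohortError(
            f"subjects row {row}: sex must be one of {SEXES}, "
            f"got {subj['sex'].iloc[row]!r}")
    lo, hi = cohort.age_range
    ages = pd.to_numeric(subj["age"], errors="coerce")
    bad_age = ages.isna() | (ages < lo) | (ages > hi)
    if bad_age.any():
        row = int(np.flatnonzero(bad_age.to_numpy())[0])
        raise CohortError(
            f"subjects row {row}: age {subj['age'].iloc[row]!r} outside "
            f"plausible range [{lo}, {hi}]")

    ids = set(subj["id"])
    cord = cohort.cord
    for col in CORD_RAW_COLUMNS:
        if col not in cord.columns:
            raise CohortError(f"cord table missing column {col!r}")
    bad_level = ~cord["level"].isin(LEVELS)
    if bad_level.any():
        row = int(np.flatnonzero(bad_level.to_numpy())[0])
        raise CohortError(
            f"cord row {row}: unknown level label {cord['level'].iloc[row]!r} "
            f"(expected one of {LEVELS})")
    unknown = ~cord["id"].isin(ids)
    if unknown.any():
        row = int(np.flatnonzero(unknown.to_numpy())[0])
        raise CohortError(f"cord row {row}: unknown subject id "
                          f"{cord['id'].iloc[row]!r}")
    dup = cord.duplicated(subset=["id", "level"])
    if dup.any():
        row = int(np.flatnonzero(dup.to_numpy())[0])
        raise CohortError(
            f"cord row {row}: duplicate (subject, level) pair "
            f"({cord['id'].iloc[row]!r}, {cord['level'].iloc[row]!r})")
    for col in ("tca_mm2", "gm_mm2"):
        vals = pd.to_numeric(cord[col], errors="coerce")
        bad = vals.notna() & (vals <= 0)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise CohortError(f"cord row {row}: nonpositive {col}")
    both = cord[["tca_mm2", "gm_mm2"]].notna().all(axis=1)
    bad = both & (cord["gm_mm2"] >= cord["tca_mm2"])
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise CohortError(
            f"cord row {row}: gm_mm2 >= tca_mm2 "
            f"({cord['gm_mm2'].iloc[row]} >= {cord['tca_mm2'].iloc[row]})")

    cov = cohort.covariates
    if len(cov):
        if "id" not in cov.columns:
            raise CohortError("covariates table missing column 'id'")
        unknown_cols = [c for c in cov.columns
                        if c not in ("id",) + COVARIATE_COLUMNS]
        if unknown_cols:
            raise CohortError(f"unknown covariate column(s) {unknown_cols}")
        unknown = ~cov["id"].isin(ids)
        if unknown.any():
            row = int(np.flatnonzero(unknown.to_numpy())[0])
            raise CohortError(f"covariates row {row}: unknown subject id "
                              f"{cov['id'].iloc[row]!r}")
        if cov["id"].duplicated().any():
            raise CohortError("duplicate subject id in covariates table")
        for col in cov.columns:
            if col == "id":
                continue
            vals = pd.to_numeric(cov[col], errors="coerce")
            bad = vals.notna() & (vals <= 0)
            if bad.any():
                row = int(np.flatnonzero(bad.to_numpy())[0])
                raise CohortError(
                    f"covariates row {row}: nonpositive {col}")


# ---------------------------------------------------------------------------
# derived metrics
# ---------------------------------------------------------------------------

def derive_metrics(cohort: Cohort) -> Cohort:
    """Populate derived cord and vertebra metrics; raw fields untouched.

    Cord: ``wm = tca − gm`` and ``gm_fraction = 100·gm/tca``.
    Vertebra (where the raw heights/diameter are present):

    * ``mean_vertebra_height = (anterior_height + posterior_height)/2``
    * ``sagittal_vertebra_area = mean_vertebra_height × ap_vertebra_diameter``
    * ``sagittal_area_trapez =
      2·[(mean_vertebra_height + middle_vertebra_height)/2 ×
      ap_vertebra_diameter/2]``

    Idempotent: applying it twice is the same as once.
    """
    cord = cohort.cord.copy()
    both = cord[["tca_mm2", "gm_mm2"]].notna().all(axis=1)
    cord.loc[both, "wm_mm2"] = cord.loc[both, "tca_mm2"] - cord.loc[both, "gm_mm2"]
    cord.loc[both, "gm_fraction"] = (
        100.0 * cord.loc[both, "gm_mm2"] / cord.loc[both, "tca_mm2"])
    if "wm_mm2" not in cord.columns:
        cord["wm_mm2"] = np.nan
    if "gm_fraction" not in cord.columns:
        cord["gm_fraction"] = np.nan

    cov = cohort.covariates.copy()
    if len(cov):
        have = [c for c in ("anterior_height", "posterior_height",
                            "ap_vertebra_diameter", "middle_vertebra_height")
                if c in cov.columns]
        if {"anterior_height", "posterior_height"} <= set(have):
            ok = cov[["anterior_height", "posterior_height"]].notna().all(axis=1)
            cov.loc[ok, "mean_vertebra_height"] = (
                cov.loc[ok, "anterior_height"] + cov.loc[ok, "posterior_height"]) / 2.0
        if "mean_vertebra_height" in cov.columns and "ap_vertebra_diameter" in cov.columns:
            ok = cov[["mean_vertebra_height", "ap_vertebra_diameter"]].notna().all(axis=1)
            cov.loc[ok, "sagittal_vertebra_area"] = (
                cov.loc[ok, "mean_vertebra_height"]
                * cov.loc[ok, "ap_vertebra_diameter"])
            if "middle_vertebra_height" in cov.columns:
                ok2 = ok & cov["middle_vertebra_height"].notna()
                cov.loc[ok2, "sagittal_area_trapez"] = 2.0 * (
                    (cov.loc[ok2, "mean_vertebra_height"]
                     + cov.loc[ok2, "middle_vertebra_height"]) / 2.0
                    * cov.loc[ok2, "ap_vertebra_diameter"] / 2.0)
    return replace(cohort, subjects=cohort.subjects, cord=cord, covariates=cov)


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

_FILES = ("subjects.csv", "cord.csv", "covariates.csv")


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write the three cohort CSVs into directory *path* (created if needed).

    Full float precision (round-trippable repr) is used so that
    write→read is the identity.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    cohort.subjects.to_csv(path / "subjects.csv", index=False,
                           float_format=None)
    cohort.cord.to_csv(path / "cord.csv", index=False)
    cohort.covariates.to_csv(path / "covariates.csv", index=False)


def read_cohort(path: str | Path, age_range: tuple[float, float] = (18.0, 100.0)) -> Cohort:
    """Read a cohort from a directory of ``subjects/cord/covariates`` CSVs.

    Empty cells map to NaN (explicit missingness); schema violations raise
    :class:`CohortError` naming the offending row.
    """
    path = Path(path)
    for fname in ("subjects.csv", "cord.csv"):
        if not (path / fname).exists():
            raise CohortError(f"missing required file {fname} in {path}")
    subjects = pd.read_csv(path / "subjects.csv", dtype={"id": str})
    cord = pd.read_csv(path / "cord.csv", dtype={"id": str})
    covp = path / "covariates.csv"
    if covp.exists():
        try:
            covariates = pd.read_csv(covp, dtype={"id": str})
        except pd.errors.EmptyDataError:
            covariates = pd.DataFrame({"id": pd.Series(dtype=str)})
        if len(covariates) == 0 and "id" not in covariates.columns:
            covariates = pd.DataFrame({"id": pd.Series(dtype=str)})
    else:
        covariates = pd.DataFrame({"id": pd.Series(dtype=str)})
    for col in ("age", "height", "weight"):
        if col in subjects.columns:
            try:
                subjects[col] = pd.to_numeric(subjects[col])
            except (ValueError, TypeError) as exc:
                raise CohortError(f"non-numeric value in subjects.{col}: {exc}")
    for col in cord.columns:
        if col in ("id", "level"):
            continue
        try:
            cord[col] = pd.to_numeric(cord[col])
        except (ValueError, TypeError) as exc:
            raise CohortError(f"non-numeric value in cord.{col}: {exc}")
    for col in covariates.columns:
        if col == "id":
            continue
        try:
            covariates[col] = pd.to_numeric(covariates[col])
        except (ValueError, TypeError) as exc:
            raise CohortError(f"non-numeric value in covariates.{col}: {exc}")
    return Cohort(subjects=subjects, cord=cord, covariates=covariates,
                  age_range=age_range)
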