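"""Generator configuration: full parametrization of the synthetic cohort.

The configuration separates the *anatomy* of the generative model —

* sex mix and per-sex (truncated-normal) age distributions,
* a per-sex multivariate-normal joint over the base covariates
  (age, TICV, AP vertebra diameter, sagittal vertebra area),
* one linear area model per (disc level, cord measure) with a direct sex
  offset and a residual scale,
* a correlation matrix for the residual vector across the eight
  (level, measure) outcomes (one draw per subject),
* one-factor models for the remaining brain/skull metrics (loading on TICV),

— from the *realization* parameters (n, seed, missingness counts).  All of
it round-trips through YAML.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .cohort import LEVELS

__all__ = ["AreaModel", "GeneratorConfig", "ConfigError",
           "OUTCOME_KEYS", "outcome_key", "nearest_psd_correlation",
           "check_correlation_matrix"]

#: canonical outcome order used for the residual correlation matrix
OUTCOME_KEYS = tuple(f"{level}:{measure}"
                     for level in LEVELS for measure in ("tca", "gm"))


def outcome_key(level: str, measure: str) -> str:
    key = f"{level}:{measure.lower()}"
    if key not in OUTCOME_KEYS:
        raise ConfigError(f"unknown outcome {level!r}/{measure!r}")
    return key


class ConfigError(ValueError):
    """Invalid generator configuration."""


@dataclass
class AreaModel:
    """Linear predictor for one (level, measure) outcome.

    area = intercept_f + sex_offset·[male] + Σ coef·covariate + ε,
    ε ~ N(0, residual_sd²) correlated across outcomes.
    """

    intercept_f: float
    sex_offset: float                 # mm², M minus F, direct (non-mediated)
    coefficients: dict[str, float]    # keyed by base covariate name
    residual_sd: float

    def linear_predictor(self, male: float, covariates: dict[str, float]) -> float:
        return (self.intercept_f + self.sex_offset * male
                + sum(c * covariates[name]
                      for name, c in self.coefficients.items()))


@dataclass
class GeneratorConfig:
    n_subjects: int
    female_fraction: float
    age_bounds: tuple[float, float]
    #: per-sex parent (mean, sd) of the normal age distribution; the draw is
    #: truncated to ``age_bounds`` by resampling
    age_parent: dict[str, tuple[float, float]]
    #: base covariate names, "age" first
    covariate_names: list[str]
    #: per-sex means for the non-age base covariates
    covariate_means: dict[str, dict[str, float]]
    #: shared SDs for the non-age base covariates
    covariate_sds: dict[str, float]
    #: correlation matrix over ``covariate_names`` (age included)
    covariate_correlations: list[list[float]]
    area_models: dict[str, AreaModel]
    #: correlation matrix over ``OUTCOME_KEYS`` for the residual vector
    residual_correlations: list[list[float]]
    #: one-factor models for additional covariates: name -> mean/sd/r_ticv
    extras: dict[str, dict[str, float]]
    #: decomposition of the derived vertebra metrics back into raw heights
    vertebra: dict[str, float] = field(default_factory=lambda: {
        "middle_ratio": 0.94, "middle_noise_sd": 0.35, "height_split_sd": 0.8})
    #: per-sex height (cm) / weight (kg) moments and their correlation
    anthropometry: dict = field(default_factory=lambda: {
        "M": {"height": (177.0, 7.0), "weight": (82.0, 12.0)},
        "F": {"height": (163.0, 6.0), "weight": (68.0, 11.0)},
        "height_weight_corr": 0.5})
    #: counts of subjects lacking thoracic cord levels / lacking covariates
    missingness: dict[str, int] = field(default_factory=lambda: {
        "thoracic": 2, "covariates": 2})
    seed: int = 0

    # ------------------------------------------------------------------
    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not 0.0 <= self.female_fraction <= 1.0:
            raise ConfigError("female_fraction must be in [0, 1]")
        if self.covariate_names[0] != "age":
            raise ConfigError("covariate_names must start with 'age'")
        k = len(self.covariate_names)
        C = np.asarray(self.covariate_correlations, dtype=float)
        if C.shape != (k, k):
            raise ConfigError("covariate_correlations shape mismatch")
        check_correlation_matrix(C, "covariate_correlations")
        R = np.asarray(self.residual_correlations, dtype=float)
        if R.shape != (len(OUTCOME_KEYS),) * 2:
            raise ConfigError("residual_correlations shape mismatch")
        check_correlation_matrix(R, "residual_correlations")
        for key, am in self.area_models.items():
            if key not in OUTCOME_KEYS:
                raise ConfigError(f"unknown outcome key {key!r}")
            if am.residual_sd < 0:
                raise ConfigError(f"negative residual sd for {key}")
            unknown = set(am.coefficients) - set(self.covariate_names)
            if unknown:
                raise ConfigError(f"{key}: coefficients for unknown "
                                  f"covariates {sorted(unknown)}")
        for name in ("thoracic", "covariates"):
            if self.missingness.get(name, 0) < 0:
                raise ConfigError("negative missingness count")

    # ------------------------------------------------------------------
    @property
    def sex_fractions(self) -> dict[str, float]:
        return {"M": 1.0 - self.female_fraction, "F": self.female_fraction}

    def covariate_mean_vector(self, sex: str) -> np.ndarray:
        """Parent mean of the base covariate vector for one sex (age first)."""
        mu = [self.age_parent[sex][0]]
        mu += [self.covariate_means[sex][n] for n in self.covariate_names[1:]]
        return np.asarray(mu, dtype=float)

    def covariate_cov_matrix(self, sex: str) -> np.ndarray:
        """Parent covariance of the base covariates for one sex."""
        sds = [self.age_parent[sex][1]]
        sds += [self.covariate_sds[n] for n in self.covariate_names[1:]]
        D = np.diag(sds)
        R = np.asarray(self.covariate_correlations, dtype=float)
        return D @ R @ D

    # ------------------------------------------------------------------
    # serialization
    # ------------------------------------------------------------------
    def to_dict(self) -> dict:
        d = _plain(dataclasses.asdict(self))
        d["age_bounds"] = list(self.age_bounds)
        d["age_parent"] = {s: list(v) for s, v in self.age_parent.items()}
        anth = {}
        for k, v in self.anthropometry.items():
            if isinstance(v, dict):
                anth[k] = {kk: list(vv) for kk, vv in v.items()}
            else:
                anth[k] = v
        d["anthropometry"] = anth
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        d["age_bounds"] = tuple(d["age_bounds"])
        d["age_parent"] = {s: tuple(v) for s, v in d["age_parent"].items()}
        if "anthropometry" in d:
            anth = {}
            for k, v in d["anthropometry"].items():
                if isinstance(v, dict):
                    anth[k] = {kk: tuple(vv) for kk, vv in v.items()}
                else:
                    anth[k] = v
            d["anthropometry"] = anth
        d["area_models"] = {k: AreaModel(**v) if isinstance(v, dict) else v
                            for k, v in d["area_models"].items()}
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False,
                           default_flow_style=None)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GeneratorConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _plain(obj):
    """Recursively convert numpy scalars/arrays to built-in types."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return type(obj)(_plain(v) for v in obj)
    if isinstance(obj, np.ndarray):
        return _plain(obj.tolist())
    if isinstance(obj, np.integer):
        return int(obj)
    if isinstance(obj, np.floating):
        return float(obj)
    return obj


# ---------------------------------------------------------------------------
# correlation matrix hygiene
# ---------------------------------------------------------------------------

def check_correlation_matrix(C: np.ndarray, name: str,
                             repair_tol: float = 1e-8) -> np.ndarray:
    """Validate symmetry/unit diagonal; repair eigenvalues within tolerance.

    Eigenvalues more negative than ``-repair_tol`` are an error; tiny
    negative eigenvalues (numerical) are clipped and the matrix is
    renormalized to unit diagonal in place.
    """
    if not np.allclose(C, C.T, atol=1e-10):
        raise ConfigError(f"{name} is not symmetric")
    if not np.allclose(np.diag(C), 1.0, atol=1e-10):
        raise ConfigError(f"{name} diagonal is not 1")
    w = np.linalg.eigvalsh(C)
    if w.min() < -repair_tol:
        raise ConfigError(
            f"{name} is not positive semi-definite "
            f"(min eigenvalue {w.min():.3g})")
    if w.min() < 0:
        C[:] = nearest_psd_correlation(C)
    return C


def nearest_psd_correlation(C: np.ndarray, floor: float = 1e-10) -> np.ndarray:
    """Eigenvalue-clipped positive semi-definite correlation matrix."""
    w, V = np.linalg.eigh((C + C.T) / 2.0)
    w = np.clip(w, floor, None)
    A = V @ np.diag(w) @ V.T
    d = np.sqrt(np.diag(A))
    A = A / np.outer(d, d)
    np.fill_diagonal(A, 1.0)
    return (A + A.T) / 2.0
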