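"""Synthetic cohort sampling from a :class:`~cordnorm.config.GeneratorConfig`.

Generation order per subject: sex → (age, TICV, vertebra metrics) from the
sex-conditional joint with age truncated by resampling → remaining brain /
skull metrics conditional on TICV → cord areas as linear predictor plus a
correlated residual vector across the eight (level, measure) outcomes.

Randomness: a single integer seed; per-subject streams are split with
``numpy.random.SeedSequence(seed, spawn_key=(subject_index,))`` so that
extending a cohort leaves earlier subjects' measurements unchanged.
Missingness assignment uses its own stream.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .calibration import build_default_config, PopulationMoments
from .cohort import (CERVICAL_LEVELS, LEVELS, THORACIC_LEVELS, Cohort,
                     derive_metrics)
from .config import (OUTCOME_KEYS, ConfigError, GeneratorConfig,
                     check_correlation_matrix)

__all__ = ["default_config", "generate_cohort", "calibrate_residuals"]

_MISSINGNESS_STREAM = 0x7FFFFFF0  # spawn key reserved for missingness draws


def default_config() -> GeneratorConfig:
    """The packaged calibration: a 32-subject cohort (14 M / 18 F, ages
    28–78) whose population moments reproduce the published level means/SDs,
    sex and age effects, covariate–area correlations, model R² and
    cross-level correlations.  See :mod:`cordnorm.calibration`.
    """
    return build_default_config()


def _subject_rng(seed: int, index: int) -> np.random.Generator:
    return np.random.Generator(
        np.random.PCG64(np.random.SeedSequence(seed, spawn_key=(index,))))


def _chol_psd(C: np.ndarray) -> np.ndarray:
    """Cholesky factor tolerant of PSD (rank-deficient) matrices."""
    try:
        return np.linalg.cholesky(C)
    except np.linalg.LinAlgError:
        w, V = np.linalg.eigh((C + C.T) / 2.0)
        w = np.clip(w, 0.0, None)
        return V @ np.diag(np.sqrt(w))


def generate_cohort(config: GeneratorConfig, n: int | None = None,
                    seed: int | None = None) -> Cohort:
    """Draw a synthetic cohort; fully reproducible given (config, n, seed).

    Parameters
    ----------
    config : generator parametrization (see :func:`default_config`).
    n : number of subjects (default ``config.n_subjects``); must be ≥ 4.
    seed : integer seed (default ``config.seed``).

    Raises
    ------
    ConfigError
        For non-PSD correlation input (beyond the repair tolerance) or when
        more than 10% of subjects require residual resampling to satisfy
        0 < gm < tca.
    """
    n = int(config.n_subjects if n is None else n)
    seed = int(config.seed if seed is None else seed)
    if n < 4:
        raise ConfigError("need n >= 4 subjects")

    cov_corr = np.asarray(config.covariate_correlations, dtype=float)
    check_correlation_matrix(cov_corr, "covariate_correlations")
    resid_corr = np.asarray(config.residual_correlations, dtype=float)
    check_correlation_matrix(resid_corr, "residual_correlations")

    base_names = list(config.covariate_names)
    k = len(base_names)
    mu = {s: config.covariate_mean_vector(s) for s in ("M", "F")}
    chol = {s: _chol_psd(config.covariate_cov_matrix(s)) for s in ("M", "F")}
    lo, hi = config.age_bounds

    sigma = np.array([config.area_models[key].residual_sd
                      for key in OUTCOME_KEYS])
    resid_chol = np.diag(sigma) @ _chol_psd(resid_corr)

    # mixture SD of ticv, for the one-factor extras
    pm_like = _ticv_mixture_sd(config)
    i_ticv = base_names.index("ticv")
    ticv_mean_overall = sum(config.sex_fractions[s] * mu[s][i_ticv]
                            for s in ("M", "F"))

    anth = config.anthropometry
    hw_r = float(anth.get("height_weight_corr", 0.0))

    rows_subj, rows_cord, rows_cov = [], [], []
    resampled = 0
    for i in range(n):
        rng = _subject_rng(seed, i)
        sex = "F" if rng.random() < config.female_fraction else "M"
        # base covariates, truncating age by resampling the whole vector
        for _try in range(1000):
            x = mu[sex] + chol[sex] @ rng.standard_normal(k)
            if lo <= x[0] <= hi and np.all(x[1:] > 0):
                break
        else:
            raise ConfigError("could not sample base covariates within bounds")
        base = dict(zip(base_names, x))

        # height / weight (no direct pathway into the areas)
        hm, hs = anth[sex]["height"]
        wm, ws = anth[sex]["weight"]
        zh, zw = rng.standard_normal(2)
        height = hm + hs * zh
        weight = wm + ws * (hw_r * zh + np.sqrt(1 - hw_r ** 2) * zw)

        # extras: one-factor on TICV
        extras = {}
        t_dev = (base["ticv"] - ticv_mean_overall) / pm_like
        for name, par in config.extras.items():
            r = float(par["r_ticv"])
            sd = float(par["sd"])
            val = (par["mean"] + r * sd * t_dev
                   + sd * np.sqrt(max(0.0, 1 - r ** 2)) * rng.standard_normal())
            extras[name] = max(val, 1e-6)

        # vertebra decomposition consistent with the derived metrics
        apd = base.get("ap_vertebra_diameter")
        sva = base.get("sagittal_vertebra_area")
        vert = {}
        if apd is not None and sva is not None:
            mvh = sva / apd
            vpar = config.vertebra
            mid = (vpar["middle_ratio"] * mvh
                   + vpar["middle_noise_sd"] * rng.standard_normal())
            split = vpar["height_split_sd"] * rng.standard_normal()
            vert = {"ap_vertebra_diameter": apd,
                    "middle_vertebra_height": max(mid, 1.0),
                    "anterior_height": mvh + split / 2.0,
                    "posterior_height": mvh - split / 2.0}

        # cord areas with correlated residuals; enforce 0 < gm < tca
        male = 1.0 if sex == "M" else 0.0
        lp = np.array([config.area_models[key].linear_predictor(male, base)
                       for key in OUTCOME_KEYS])
        for _try in range(100):
            eps = resid_chol @ rng.standard_normal(len(OUTCOME_KEYS))
            areas = lp + eps
            ok = True
            for j in range(0, len(OUTCOME_KEYS), 2):
                tca, gm = areas[j], areas[j + 1]
                if not (0.0 < gm < tca):
                    ok = False
                    break
            if ok:
                break
            if _try == 0:
                resampled += 1
        else:
            raise ConfigError("residual resampling failed to satisfy "
                              "0 < gm < tca")

        sid = f"S{i + 1:04d}"
        rows_subj.append({"id": sid, "sex": sex, "age": base["age"],
                          "height": height, "weight": weight})
        for li, level in enumerate(LEVELS):
            rows_cord.append({"id": sid, "level": level,
                              "tca_mm2": areas[2 * li],
                              "gm_mm2": areas[2 * li + 1]})
        covrow = {"id": sid, "ticv": base["ticv"]}
        covrow.update(extras)
        covrow.update(vert)
        rows_cov.append(covrow)

    if resampled > 0.10 * n:
        raise ConfigError(
            f"infeasible area constraints: {resampled}/{n} subjects "
            "needed residual resampling")

    subjects = pd.DataFrame(rows_subj)
    cord = pd.DataFrame(rows_cord)
    covariates = pd.DataFrame(rows_cov)

    # missingness: separate stream; thoracic-missing and covariate-missing
    # subject sets are disjoint
    n_thor = int(config.missingness.get("thoracic", 0))
    n_cov = int(config.missingness.get("covariates", 0))
    if n_thor + n_cov > 0:
        if n_thor + n_cov > n:
            raise ConfigError("missingness counts exceed cohort size")
        mrng = np.random.Generator(np.random.PCG64(
            np.random.SeedSequence(seed, spawn_key=(_MISSINGNESS_STREAM,))))
        picked = mrng.permutation(n)[:n_thor + n_cov]
        thor_ids = {f"S{i + 1:04d}" for i in picked[:n_thor]}
        cov_ids = {f"S{i + 1:04d}" for i in picked[n_thor:]}
        if thor_ids:
            drop = cord["id"].isin(thor_ids) & cord["level"].isin(THORACIC_LEVELS)
            cord = cord[~drop]
        if cov_ids:
            covariates = covariates[~covariates["id"].isin(cov_ids)]

    cohort = Cohort(subjects=subjects, cord=cord, covariates=covariates,
                    age_range=(min(18.0, lo), max(100.0, hi)))
    return derive_metrics(cohort)


def _ticv_mixture_sd(config: GeneratorConfig) -> float:
    """Whole-cohort (sex-mixture, age-truncated) SD of TICV."""
    pm = PopulationMoments(config)
    i = pm.names.index("ticv")
    return float(np.sqrt(pm.cov[i, i]))


def calibrate_residuals(config: GeneratorConfig,
                        targets: dict[str, tuple[list[str], float]],
                        ) -> GeneratorConfig:
    """Solve residual SDs so specified covariate models reach target R².

    Parameters
    ----------
    config : configuration whose area-model coefficients and covariate
        moments are taken as fixed.
    targets : mapping ``outcome key -> (covariate names, target)`` where the
        target is either a population R² in (0, 1), or a dict
        ``{"adj_r2": value, "n": n, "p": p}`` to be converted with
        R² = 1 − (1−adjR²)(n−p−1)/(n−1).

    The population R² of the covariate model is Q/(V₀+σ²), with Q the
    variance captured by the population OLS on those covariates and V₀ the
    systematic outcome variance, giving σ² = Q/R² − V₀ in closed form.
    (When the covariates coincide with the generative predictor this reduces
    to R² = var(lp)/(var(lp)+σ²).)

    Returns a new configuration; the input is not mutated.
    """
    new = GeneratorConfig.from_dict(config.to_dict())
    pm = PopulationMoments(new)
    for key, (covariates, target) in targets.items():
        if key not in new.area_models:
            raise ConfigError(f"unknown outcome key {key!r}")
        if isinstance(target, dict):
            n, p = int(target["n"]), int(target["p"])
            target = 1.0 - (1.0 - float(target["adj_r2"])) * (n - p - 1) / (n - 1)
        target = float(target)
        if not 0.0 < target < 1.0:
            raise ConfigError(f"target R² for {key} must be in (0, 1), "
                              f"got {target}")
        level, measure = key.split(":")
        q = pm.explained_variance(level, measure, covariates)
        w, am = pm._w(key)
        v0 = float(w @ pm.cov @ w)
        sigma2 = q / target - v0
        if sigma2 <= 0:
            raise ConfigError(
                f"target R²={target:.3f} for {key} is unreachable: the "
                "systematic variance alone exceeds Q/R²")
        new.area_models[key].residual_sd = float(np.sqrt(sigma2))
    return new
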