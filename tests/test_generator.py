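"""Synthetic cohort generator: reproducibility, moments, missingness, config."""

import numpy as np
import pandas as pd
import pytest

from cordnorm import (ConfigError, GeneratorConfig, calibrate_residuals,
                      default_config, generate_cohort)
from cordnorm.config import OUTCOME_KEYS, AreaModel


def _minimal_config(**overrides):
    """Deterministic minimal config: no effects unless overridden."""
    names = ["age", "ticv", "ap_vertebra_diameter", "sagittal_vertebra_area"]
    models = {}
    for key in OUTCOME_KEYS:
        base = 80.0 if key.endswith("tca") else 20.0
        models[key] = AreaModel(intercept_f=base, sex_offset=0.0,
                                coefficients={}, residual_sd=0.0)
    cfg = dict(
        n_subjects=8,
        female_fraction=0.5,
        age_bounds=(28.0, 78.0),
        age_parent={"M": (48.0, 10.0), "F": (50.0, 10.0)},
        covariate_names=names,
        covariate_means={s: {"ticv": 1.4e6, "ap_vertebra_diameter": 15.6,
                             "sagittal_vertebra_area": 200.0}
                         for s in ("M", "F")},
        covariate_sds={"ticv": 1e5, "ap_vertebra_diameter": 1.2,
                       "sagittal_vertebra_area": 20.0},
        covariate_correlations=np.eye(4).tolist(),
        area_models=models,
        residual_correlations=np.eye(8).tolist(),
        extras={},
        missingness={"thoracic": 0, "covariates": 0},
    )
    cfg.update(overrides)
    return GeneratorConfig(**cfg)


class TestReproducibility:
    def test_same_seed_identical_cohorts(self, default_cfg):
        a = generate_cohort(default_cfg, n=32, seed=5)
        b = generate_cohort(default_cfg, n=32, seed=5)
        pd.testing.assert_frame_equal(a.subjects, b.subjects)
        pd.testing.assert_frame_equal(a.cord, b.cord)
        pd.testing.assert_frame_equal(a.covariates, b.covariates)

    def test_different_seed_differs(self, default_cfg):
        a = generate_cohort(default_cfg, n=32, seed=5)
        b = generate_cohort(default_cfg, n=32, seed=6)
        assert not np.allclose(a.subjects["age"], b.subjects["age"])

    def test_adding_subjects_preserves_earlier_ones(self, default_cfg):
        small = generate_cohort(default_cfg, n=10, seed=5)
        large = generate_cohort(default_cfg, n=16, seed=5)
        np.testing.assert_array_equal(small.subjects["age"],
                                      large.subjects["age"].iloc[:10])
        small_cord = small.cord.sort_values(["id", "level"]).reset_index(drop=True)
        large_cord = (large.cord[large.cord["id"].isin(small.subjects["id"])]
                      .sort_values(["id", "level"]).reset_index(drop=True))
        # cord measurements of shared subjects are identical; only the
        # missingness assignment may differ with n
        merged = small_cord.merge(large_cord, on=["id", "level"],
                                  suffixes=("_s", "_l"))
        np.testing.assert_allclose(merged["tca_mm2_s"], merged["tca_mm2_l"])


class TestDegenerateConfig:
    def test_zero_noise_zero_effects_yields_intercepts(self):
        cfg = _minimal_config()
        cohort = generate_cohort(cfg, n=6, seed=0)
        tca = cohort.cord.loc[cohort.cord["level"] == "C2-C3", "tca_mm2"]
        np.testing.assert_allclose(tca, 80.0)
        gm = cohort.cord.loc[cohort.cord["level"] == "T9-T10", "gm_mm2"]
        np.testing.assert_allclose(gm, 20.0)

    def test_n_below_minimum(self, default_cfg):
        with pytest.raises(ConfigError, match="n >= 4"):
            generate_cohort(default_cfg, n=3, seed=0)

    def test_infeasible_area_constraint(self):
        # GM intercept above TCA forces resampling beyond the allowed rate
        cfg = _minimal_config()
        cfg.area_models["C2-C3:gm"].intercept_f = 90.0
        cfg.area_models["C2-C3:gm"].residual_sd = 1.0
        cfg.area_models["C2-C3:tca"].residual_sd = 1.0
        with pytest.raises(ConfigError, match="resampling"):
            generate_cohort(cfg, n=8, seed=0)

    def test_non_psd_residual_correlations_rejected(self):
        bad = np.eye(8)
        bad[0, 1] = bad[1, 0] = 0.9
        bad[0, 2] = bad[2, 0] = 0.9
        bad[1, 2] = bad[2, 1] = -0.9
        with pytest.raises(ConfigError, match="positive semi-definite"):
            _minimal_config(residual_correlations=bad.tolist())


class TestMissingness:
    def test_counts_match_config_exactly(self, default_cfg):
        cohort = generate_cohort(default_cfg, n=32, seed=3)
        n_thor = default_cfg.missingness["thoracic"]
        n_cov = default_cfg.missingness["covariates"]
        thoracic = cohort.cord[cohort.cord["level"].isin(["T8-T9", "T9-T10"])]
        missing_thor = set(cohort.subjects["id"]) - set(thoracic["id"])
        assert len(missing_thor) == n_thor
        missing_cov = set(cohort.subjects["id"]) - set(cohort.covariates["id"])
        assert len(missing_cov) == n_cov
        # the two missingness groups are disjoint subjects
        assert not (missing_thor & missing_cov)

    def test_cervical_levels_complete(self, default_cfg):
        cohort = generate_cohort(default_cfg, n=32, seed=3)
        for level in ("C2-C3", "C3-C4"):
            assert (cohort.cord["level"] == level).sum() == 32


class TestLargeSampleConvergence:
    """Empirical moments of a 20 000-subject cohort vs configured values."""

    def test_level_means_and_sds(self, default_cfg, big_cohort):
        df = big_cohort.analysis_frame()
        assert df["tca_c2c3"].mean() == pytest.approx(79.7, abs=0.5)
        assert df["tca_c2c3"].std() == pytest.approx(7.0, abs=0.25)
        assert df["gm_c2c3"].mean() == pytest.approx(19.4, abs=0.15)
        assert df["tca_t9t10"].mean() == pytest.approx(45.3, abs=0.3)

    def test_cross_level_residual_structure(self, big_cohort):
        df = big_cohort.analysis_frame()
        r = df[["tca_c2c3", "tca_c3c4"]].corr().iloc[0, 1]
        assert r == pytest.approx(0.89, abs=0.03)
        r_thor = df[["tca_t8t9", "tca_t9t10"]].corr().iloc[0, 1]
        assert r_thor == pytest.approx(0.89, abs=0.03)

    def test_covariate_moments(self, default_cfg, big_cohort):
        df = big_cohort.analysis_frame()
        lo, hi = default_cfg.age_bounds
        assert df["age"].between(lo, hi).all()
        # sex-conditional TICV means match the configured ones
        for sex in ("M", "F"):
            target = default_cfg.covariate_means[sex]["ticv"]
            got = df.loc[df["sex"] == sex, "ticv"].mean()
            # truncation-induced shift through the age pathway is small
            assert got == pytest.approx(target, rel=0.01)

    def test_parameter_recovery_by_regression(self, default_cfg, big_cohort):
        """OLS on the generative covariates recovers the configured slopes."""
        import statsmodels.api as sm
        df = big_cohort.analysis_frame()
        am = default_cfg.area_models["C2-C3:tca"]
        covs = list(am.coefficients)
        cols = [c if c != "age" else "age" for c in covs]
        sub = df[["tca_c2c3", "sex_male", *cols]].dropna()
        X = sm.add_constant(sub[["sex_male", *cols]].to_numpy())
        res = sm.OLS(sub["tca_c2c3"].to_numpy(), X).fit()
        assert res.params[1] == pytest.approx(am.sex_offset, abs=0.35)
        for i, c in enumerate(covs):
            tol = 4.5 * res.bse[2 + i]
            assert res.params[2 + i] == pytest.approx(am.coefficients[c],
                                                      abs=tol)

    def test_derived_vertebra_metrics_consistent(self, big_cohort):
        cov = big_cohort.covariates
        np.testing.assert_allclose(
            cov["mean_vertebra_height"] * cov["ap_vertebra_diameter"],
            cov["sagittal_vertebra_area"], rtol=1e-9)


class TestCalibrateResiduals:
    def test_closed_form_single_pathway(self):
        # one covariate pathway: var(lp)=1 target R²=0.5 -> sigma²=1
        cfg = _minimal_config()
        key = "C2-C3:tca"
        b = 1.0 / 1e5  # coefficient * sd(ticv) = 1
        cfg.area_models[key] = AreaModel(intercept_f=80.0, sex_offset=0.0,
                                         coefficients={"ticv": b},
                                         residual_sd=5.0)
        out = calibrate_residuals(cfg, {key: (["ticv"], 0.5)})
        assert out.area_models[key].residual_sd == pytest.approx(1.0, rel=1e-9)
        # input untouched
        assert cfg.area_models[key].residual_sd == 5.0

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.2, 1.7])
    def test_target_out_of_range(self, bad):
        cfg = _minimal_config()
        cfg.area_models["C2-C3:tca"].coefficients = {"ticv": 1e-5}
        with pytest.raises((ConfigError, ValueError)):
            calibrate_residuals(cfg, {"C2-C3:tca": (["ticv"], bad)})

    def test_adj_r2_target_verified_by_simulation(self, default_cfg):
        """Solving for an adjusted-R²-converted target is confirmed by a
        brute-force large-sample regression."""
        import statsmodels.api as sm
        covs = ["age", "ticv", "sagittal_vertebra_area"]
        target = {"adj_r2": 0.47, "n": 30, "p": 3}
        pop_r2 = 1 - (1 - 0.47) * (30 - 3 - 1) / (30 - 1)
        out = calibrate_residuals(default_cfg, {"C2-C3:tca": (covs, target)})
        cohort = generate_cohort(out, n=20_000, seed=21)
        df = cohort.analysis_frame()
        sub = df[["tca_c2c3", *covs]].dropna()
        X = sm.add_constant(sub[covs].to_numpy())
        res = sm.OLS(sub["tca_c2c3"].to_numpy(), X).fit()
        assert res.rsquared == pytest.approx(pop_r2, abs=0.02)


class TestConfigSerialization:
    def test_yaml_round_trip(self, default_cfg, tmp_path):
        path = tmp_path / "cfg.yaml"
        default_cfg.to_yaml(path)
        back = GeneratorConfig.from_yaml(path)
        assert back.to_dict() == default_cfg.to_dict()

    def test_default_config_shape(self, default_cfg):
        assert default_cfg.n_subjects == 32
        assert default_cfg.female_fraction == pytest.approx(18 / 32)
        assert default_cfg.age_parent["M"] == (46.8, 13.4)
        assert set(default_cfg.area_models) == set(OUTCOME_KEYS)
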