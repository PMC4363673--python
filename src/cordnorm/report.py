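"""End-to-end analysis: simulate → describe → adjust → normalize, with a manifest.

:func:`run_full_analysis` executes every stage on a generated (or supplied)
cohort and writes CSV analogues of the descriptive, adjusted-means and
normalization tables, the fitted model YAMLs, and a JSON summary comparing
the computed headline numbers against the packaged published reference
values.  Outputs are deterministic for fixed (config, seed).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .adjusted_means import covariate_screen, ls_means, median_split
from .cohort import (CERVICAL_LEVELS, LEVELS, Cohort, column_for,
                     read_cohort, write_cohort)
from .config import GeneratorConfig
from .descriptive import correlation_table, rsd, shapiro_wilk
from .generator import default_config, generate_cohort
from .normalization import (SKULL_VERTEBRA_METRICS, fit_model,
                            screen_predictors, transfer_model)

__all__ = ["RunManifest", "run_full_analysis", "describe_cohort",
           "adjusted_tables", "normalization_analysis",
           "CANONICAL_MODELS"]

BRAIN_VOLUMES = ("total_cortex", "subcortical_gm", "total_gm", "total_wm",
                 "brain")

#: the published model line-up at the reference level
CANONICAL_MODELS = {
    "tca": {
        "model1": ("ticv", "sagittal_vertebra_area"),
        "model2": ("age", "ticv", "ap_vertebra_diameter"),
        "model3": ("age", "ticv", "sagittal_vertebra_area"),
    },
    "gm": {
        "model1": ("ticv", "sagittal_vertebra_area"),
        "model2a": ("ticv", "ap_vertebra_diameter"),
    },
}

#: published headline values the run summary compares against
REFERENCE_SUMMARY = {
    "reduction_C2-C3_tca_model2": 27.0,
    "reduction_C2-C3_gm_model2a": 25.0,
    "mean_tca_C2-C3": 79.7,
    "adj_r2_C2-C3_tca_model3": 0.47,
}


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def describe_cohort(cohort: Cohort) -> dict[str, pd.DataFrame]:
    """Descriptive tables: moments, normality, and correlation tables."""
    frame = cohort.analysis_frame()
    rows = []
    for level in LEVELS:
        for meas in ("tca", "gm", "wm", "gmfrac"):
            col = f"{meas}_{level.replace('-', '').lower()}"
            v = frame[col].dropna()
            if len(v) < 2:
                continue
            rows.append({"level": level, "measure": meas, "n": len(v),
                         "mean": v.mean(), "sd": v.std(ddof=1),
                         "rsd_pct": rsd(v)})
    moments = pd.DataFrame(rows)

    norm_rows = []
    for level in LEVELS:
        for meas in ("tca", "gm", "wm", "gmfrac"):
            col = f"{meas}_{level.replace('-', '').lower()}"
            v = frame[col].dropna()
            if len(v) >= 3 and np.ptp(v) > 0:
                w, p = shapiro_wilk(v)
                norm_rows.append({"variable": col, "n": len(v),
                                  "shapiro_w": w, "p": p,
                                  "normal_at_0.05": p > 0.05})
    normality = pd.DataFrame(norm_rows)

    cord_cols = [column_for(lv, m) for lv in LEVELS for m in ("tca", "gm")]
    cross = correlation_table(frame, cord_cols, cord_cols)

    ref_rows = [column_for(lv, m) for lv in ("C2-C3", "T9-T10")
                for m in ("tca", "gm")]
    brain_cols = [c for c in BRAIN_VOLUMES if frame[c].notna().sum() >= 3]
    skel_cols = [c for c in SKULL_VERTEBRA_METRICS
                 if c in frame.columns and frame[c].notna().sum() >= 3]
    brain = correlation_table(frame, ref_rows, brain_cols) if brain_cols else None
    skel = correlation_table(frame, ref_rows, skel_cols) if skel_cols else None

    out = {"level_moments": moments, "normality": normality,
           "cross_level_r": cross.r, "cross_level_p": cross.p,
           "cross_level_n": cross.n}
    if brain is not None:
        out["brain_correlations_r"] = brain.r
        out["brain_correlations_p"] = brain.p
    if skel is not None:
        out["skeletal_correlations_r"] = skel.r
        out["skeletal_correlations_p"] = skel.p
    return out


def adjusted_tables(cohort: Cohort) -> dict[str, pd.DataFrame]:
    """Sex and age-group least-square-means comparisons plus the screen."""
    frame = cohort.analysis_frame()
    age_labels, cutoff = median_split(frame["age"], label="age_group")
    frame = frame.assign(age_group=age_labels)
    lo_lab, hi_lab = f"< {cutoff:g}", f">= {cutoff:g}"

    def comparison_rows(factor, covariates, levels):
        rows = []
        for level in ("C2-C3", "T9-T10"):
            for meas in ("tca", "wm", "gm", "gmfrac"):
                col = f"{meas}_{level.replace('-', '').lower()}"
                res = ls_means(frame, col, factor, covariates, levels=levels)
                first, second = res.levels
                rows.append({
                    "level": level, "measure": meas,
                    "group_high": first, "adj_mean_high": res.adjusted_means[first],
                    "se_high": res.se_means[first],
                    "group_low": second, "adj_mean_low": res.adjusted_means[second],
                    "se_low": res.se_means[second],
                    "difference": res.difference, "se_diff": res.se_difference,
                    "p": res.pvalue, "ci_low": res.conf_int[0],
                    "ci_high": res.conf_int[1], "n": res.n})
        return pd.DataFrame(rows)

    sex_table = comparison_rows("sex", ["age"], ("M", "F"))
    age_table = comparison_rows("age_group", ["sex_male"], (lo_lab, hi_lab))

    screen_rows = []
    for level in ("C2-C3", "T9-T10"):
        for meas in ("tca", "gm"):
            col = f"{meas}_{level.replace('-', '').lower()}"
            sc = covariate_screen(frame, col)
            sc.insert(0, "measure", meas)
            sc.insert(0, "level", level)
            screen_rows.append(sc)
    screen = pd.concat(screen_rows, ignore_index=True)
    return {"sex_comparisons": sex_table, "age_comparisons": age_table,
            "demographic_screen": screen, "age_cutoff":
            pd.DataFrame([{"median_age_cutoff": cutoff}])}


def normalization_analysis(cohort: Cohort, reference_level: str = "C2-C3"
                           ) -> dict:
    """Screen, fit, gate, evaluate and transfer the normalization models."""
    frame = cohort.analysis_frame()
    ref_rows = [column_for(reference_level, m) for m in ("tca", "gm")]
    candidates = [c for c in SKULL_VERTEBRA_METRICS
                  if c in frame.columns and frame[c].notna().sum() >= 3]
    corr = correlation_table(frame, ref_rows, candidates)
    # screen on metric names; table columns are already metric names
    selected = screen_predictors(corr)

    models, rows = {}, []
    for meas, model_defs in CANONICAL_MODELS.items():
        for name, covs in model_defs.items():
            res = fit_model(cohort, f"{reference_level}:{meas}", list(covs))
            ev = res.evaluate()
            models[f"{reference_level}:{meas}:{name}"] = res
            rows.append({"level": reference_level, "measure": meas,
                         "model": name, "covariates": "+".join(covs),
                         "n": res.n, "r2": res.r2, "adj_r2": res.adj_r2,
                         "passes_gate": res.passes_gate,
                         "rsd_meas_pct": ev.rsd_meas,
                         "rsd_norm_pct": ev.rsd_norm,
                         "reduction_pct": ev.reduction})
    reference_table = pd.DataFrame(rows)

    transfer_rows = []
    other_levels = [lv for lv in LEVELS if lv != reference_level]
    transfers = (("tca", "model3"), ("tca", "model2"), ("gm", "model2a"))
    for meas, name in transfers:
        covs = CANONICAL_MODELS[meas][name]
        for level in other_levels:
            res, ev = transfer_model(list(covs), level, cohort, measure=meas)
            models[f"{level}:{meas}:{name}"] = res
            transfer_rows.append({
                "level": level, "measure": meas, "model": name,
                "covariates": "+".join(res.covariates), "n": res.n,
                "adj_r2": res.adj_r2, "passes_gate": res.passes_gate,
                "rsd_meas_pct": ev.rsd_meas, "rsd_norm_pct": ev.rsd_norm,
                "reduction_pct": ev.reduction})
    transfer_table = pd.DataFrame(transfer_rows)

    return {"screen_correlations_r": corr.r, "screen_correlations_p": corr.p,
            "selected_covariates": selected, "reference_models": reference_table,
            "transferred_models": transfer_table, "models": models}


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

@dataclass
class RunManifest:
    seed: int
    config_sha256: str
    package_version: str
    stages: dict[str, list[str]] = field(default_factory=dict)
    timestamp: str = ""

    def to_json(self, path: Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)


def _write_tables(tables: dict, outdir: Path, stage: str,
                  manifest: RunManifest, index_keys=()) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    files = []
    for name, obj in tables.items():
        if not isinstance(obj, pd.DataFrame):
            continue
        fname = f"{name}.csv"
        obj.to_csv(outdir / fname, index=name in index_keys)
        files.append(str(outdir / fname))
    manifest.stages[stage] = sorted(files)


def run_full_analysis(config: GeneratorConfig | None = None,
                      seed: int = 0, outdir: str | Path = "cordnorm-run",
                      cohort_dir: str | Path | None = None,
                      log=print) -> RunManifest:
    """Run every pipeline stage and write all outputs under ``outdir``.

    With ``cohort_dir`` the simulation stage is skipped and the cohort CSVs
    are read from there instead.  Partial outputs are removed on failure.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if config is None:
        config = default_config()
    cfg_digest = hashlib.sha256(
        json.dumps(config.to_dict(), sort_keys=True).encode()).hexdigest()
    manifest = RunManifest(seed=int(seed), config_sha256=cfg_digest,
                           package_version=__version__,
                           timestamp=time.strftime("%Y-%m-%dT%H:%M:%S"))
    written: list[Path] = []
    stage = "simulate"
    try:
        if cohort_dir is None:
            log(f"[simulate] generating n={config.n_subjects} seed={seed}")
            cohort = generate_cohort(config, seed=seed)
            cdir = outdir / "cohort"
            write_cohort(cohort, cdir)
            manifest.stages["simulate"] = sorted(
                str(cdir / f) for f in ("subjects.csv", "cord.csv",
                                        "covariates.csv"))
        else:
            log(f"[simulate] skipped; reading cohort from {cohort_dir}")
            cohort = read_cohort(cohort_dir)
            manifest.stages["simulate"] = []

        stage = "describe"
        log(f"[describe] n={cohort.n_subjects}")
        desc = describe_cohort(cohort)
        _write_tables(desc, outdir / "describe", "describe", manifest,
                      index_keys={"cross_level_r", "cross_level_p",
                                  "cross_level_n", "brain_correlations_r",
                                  "brain_correlations_p",
                                  "skeletal_correlations_r",
                                  "skeletal_correlations_p"})

        stage = "adjust"
        adj = adjusted_tables(cohort)
        log(f"[adjust] median age cutoff "
            f"{adj['age_cutoff']['median_age_cutoff'].iloc[0]:g}")
        _write_tables(adj, outdir / "adjust", "adjust", manifest)

        stage = "normalize"
        norm = normalization_analysis(cohort)
        log(f"[normalize] selected covariates: "
            f"{', '.join(norm['selected_covariates']) or '(none)'}")
        ndir = outdir / "normalize"
        _write_tables(norm, ndir, "normalize", manifest,
                      index_keys={"screen_correlations_r",
                                  "screen_correlations_p"})
        files = manifest.stages["normalize"]
        for key, res in norm["models"].items():
            fname = ndir / (key.replace(":", "_") + ".yaml")
            res.to_yaml(fname)
            files.append(str(fname))
        sel = ndir / "selected_covariates.txt"
        sel.write_text("\n".join(norm["selected_covariates"]) + "\n")
        files.append(str(sel))

        stage = "summary"
        ref = norm["reference_models"]
        summary = {"computed": {}, "reference": dict(REFERENCE_SUMMARY)}
        pick = ref[(ref.measure == "tca") & (ref.model == "model2")]
        summary["computed"]["reduction_C2-C3_tca_model2"] = float(
            pick["reduction_pct"].iloc[0])
        pick = ref[(ref.measure == "gm") & (ref.model == "model2a")]
        summary["computed"]["reduction_C2-C3_gm_model2a"] = float(
            pick["reduction_pct"].iloc[0])
        mom = desc["level_moments"]
        summary["computed"]["mean_tca_C2-C3"] = float(
            mom[(mom.level == "C2-C3") & (mom.measure == "tca")]["mean"].iloc[0])
        pick = ref[(ref.measure == "tca") & (ref.model == "model3")]
        summary["computed"]["adj_r2_C2-C3_tca_model3"] = float(
            pick["adj_r2"].iloc[0])
        with open(outdir / "summary.json", "w", encoding="utf-8") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
        manifest.stages["summary"] = [str(outdir / "summary.json")]

        manifest.to_json(outdir / "manifest.json")
        log(f"[done] manifest written to {outdir / 'manifest.json'}")
        return manifest
    except Exception as exc:
        # remove partial outputs of the failed stage, then re-raise with stage
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
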