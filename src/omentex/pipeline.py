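"""End-to-end orchestration: simulate -> extract -> stats -> ROC -> validate.

The pipeline mirrors the reference study's analysis flow on synthetic data:
texture features are compared between matched groups of the test cohort
(univariate table with Bonferroni adjustment), the candidate predictors are
entered into conditional logistic regression, the score of interest is
evaluated by ROC analysis with the furthest-from-diagonal cutoff on the
test cohort, and that frozen cutoff is applied to the validation cohort.

Every run is a pure function of (config, seed): rerunning with the same
configuration produces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .io import write_cohort_csv, write_image_png, write_roi_json
from .roc import REFERENCE_ROC_VARIANTS, apply_cutoff, optimal_cutoff, roc_curve
from .simulate import SimConfig, gen_cohort, gen_feature_table
from .stats import clogit_fit, univariate_table
from .texture import extract_features

__all__ = ["PipelineConfig", "RunReport", "run_pipeline", "extract_cohort_features"]

DEFAULT_CLOGIT_COVARIATES = ("average", "correlation", "entropy", "std_dev")


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration for a full pipeline run."""

    sim: SimConfig = field(default_factory=SimConfig)
    source: str = "images"  # "images" | "features"
    glcm_distance: int = 1
    glcm_levels: int | None = None
    correlation_variant: str = "paper_scale"
    alpha: float = 0.05
    m_comparisons: int = 12
    clogit_covariates: tuple[str, ...] = DEFAULT_CLOGIT_COVARIATES
    score_variable: str = "entropy"
    outdir: str = "results/pipeline"
    save_images: bool = False

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sim"] = dataclasses.asdict(self.sim)
        d["sim"]["clinical_margins"] = dict(d["sim"]["clinical_margins"])
        return d


@dataclass
class RunReport:
    """Machine-readable record of one pipeline run."""

    version: str
    config: dict
    seed: int
    outputs: dict[str, str] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    summary: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True, default=_jsonable)


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def extract_cohort_features(
    cohort: pd.DataFrame,
    images: dict,
    distance: int = 1,
    levels: int | None = None,
    correlation_variant: str = "paper_scale",
) -> pd.DataFrame:
    """Append the seven texture features to a cohort table from its images."""
    rows = []
    for pid in cohort["patient_id"]:
        image, verts = images[pid]
        fs = extract_features(
            image, verts, distance=distance, levels=levels, correlation_variant=correlation_variant
        )
        rows.append(fs.as_dict())
    feats = pd.DataFrame(rows, index=cohort.index)
    return pd.concat([cohort, feats], axis=1)


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute the full analysis and write all artifacts under ``config.outdir``."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport(version=__version__, config=config.as_dict(), seed=config.sim.seed)

    # --- stage 1: simulate (or feature-level simulate) -------------------
    try:
        if config.source == "images":
            test, validation, images = gen_cohort(config.sim, with_images=True)
            test = extract_cohort_features(
                test, images, config.glcm_distance, config.glcm_levels, config.correlation_variant
            )
            validation = extract_cohort_features(
                validation, images, config.glcm_distance, config.glcm_levels, config.correlation_variant
            )
            if config.save_images:
                img_dir = outdir / "images"
                img_dir.mkdir(exist_ok=True)
                for pid, (image, verts) in sorted(images.items()):
                    write_image_png(image, img_dir / f"{pid}.png")
                    write_roi_json(verts, img_dir / f"{pid}_roi.json")
                report.outputs["images_dir"] = str(img_dir)
        elif config.source == "features":
            test, validation = gen_feature_table(config.sim)
        else:
            raise ValueError(f"unknown source {config.source!r}")
    except Exception as exc:
        raise RuntimeError(f"stage 'simulate' failed: {exc}") from exc

    corr_col = (
        "correlation_standard" if config.correlation_variant == "standard" else "correlation_paper_scale"
    )
    for name, df in [("test", test), ("validation", validation)]:
        path = outdir / f"{name}_cohort.csv"
        write_cohort_csv(df, path)
        report.outputs[f"{name}_cohort"] = str(path)

    # --- stage 2: univariate table --------------------------------------
    try:
        table1 = univariate_table(
            test, alpha=config.alpha, m=config.m_comparisons, correlation_column=corr_col
        )
    except Exception as exc:
        raise RuntimeError(f"stage 'univariate' failed: {exc}") from exc
    t1_path = outdir / "table1.csv"
    table1.to_csv(t1_path, index=False)
    report.outputs["table1"] = str(t1_path)
    n_sig = int(table1["significant"].sum())
    report.summary["univariate_significant"] = n_sig
    if n_sig == 0:
        report.warnings.append("no univariately significant variable at the Bonferroni level")
    for row in table1.itertuples():
        if row.test == "wilcoxon_signed_rank" and row.p_value == 1.0 and row.statistic == 0.0:
            report.warnings.append(f"degenerate signed-rank test for {row.variable}")

    # --- stage 3: conditional logistic regression ------------------------
    covs = [corr_col if c == "correlation" else c for c in config.clogit_covariates]
    try:
        fit = clogit_fit(test, covs)
    except Exception as exc:
        raise RuntimeError(f"stage 'clogit' failed: {exc}") from exc
    t2 = fit.summary_frame().reset_index(names="covariate")
    t2_path = outdir / "table2.csv"
    t2.to_csv(t2_path, index=False)
    report.outputs["table2"] = str(t2_path)
    report.summary["clogit_converged"] = fit.converged
    if fit.separation_detected:
        report.warnings.append("conditional logistic regression: separation detected, no estimates")
    if fit.zero_information:
        report.warnings.append(f"clogit covariates with no within-pair variation: {fit.zero_information}")

    # --- stage 4: ROC + cutoff on the test cohort ------------------------
    score_col = corr_col if config.score_variable == "correlation" else config.score_variable
    try:
        curve = roc_curve(test[score_col], test["group"])
        cut = optimal_cutoff(curve)
    except Exception as exc:
        raise RuntimeError(f"stage 'roc' failed: {exc}") from exc
    pd.DataFrame(
        {
            "threshold": curve.thresholds,
            "sensitivity": curve.sensitivity,
            "specificity": curve.specificity,
        }
    ).to_csv(outdir / "roc_points.csv", index=False)
    report.outputs["roc_points"] = str(outdir / "roc_points.csv")
    if cut.degenerate:
        report.warnings.append("degenerate ROC: no threshold separates the groups (J = 0)")

    roc_summary = {
        "score_variable": config.score_variable,
        "auc": curve.auc,
        "auc_ci_95": list(curve.auc_ci_95),
        "n_cases": curve.n_cases,
        "n_controls": curve.n_controls,
        "cutoff": cut.threshold,
        "cutoff_midpoint": cut.threshold_midpoint,
        "rule": cut.rule,
        "youden_j": cut.youden_j,
        "test_sensitivity": cut.sensitivity,
        "test_specificity": cut.specificity,
        "test_ppv": cut.ppv,
        "test_npv": cut.npv,
        "reference_variants_flag": (
            "reference-study values for this ROC disagree between its text and its summary table; "
            "both variants are listed under 'reference_variants'"
        ),
        "reference_variants": REFERENCE_ROC_VARIANTS,
    }

    # --- stage 5: frozen cutoff on the validation cohort ------------------
    try:
        conf, metrics = apply_cutoff(validation[score_col], validation["group"], cut.threshold)
    except Exception as exc:
        raise RuntimeError(f"stage 'validate' failed: {exc}") from exc
    pd.DataFrame(
        [
            {"classified": "positive", "occult": conf.tp, "control": conf.fp},
            {"classified": "negative", "occult": conf.fn, "control": conf.tn},
        ]
    ).to_csv(outdir / "confusion.csv", index=False)
    report.outputs["confusion"] = str(outdir / "confusion.csv")
    roc_summary["validation"] = {
        "tp": conf.tp,
        "fp": conf.fp,
        "fn": conf.fn,
        "tn": conf.tn,
        "sensitivity": metrics["sensitivity"],
        "specificity": metrics["specificity"],
        "ppv": metrics["ppv"],
        "npv": metrics["npv"],
    }
    rs_path = outdir / "roc_summary.json"
    rs_path.write_text(json.dumps(roc_summary, indent=2, sort_keys=True, default=_jsonable) + "\n")
    report.outputs["roc_summary"] = str(rs_path)

    report.summary.update(
        {
            "auc": curve.auc,
            "cutoff": cut.threshold,
            "test_sensitivity": cut.sensitivity,
            "test_specificity": cut.specificity,
            "validation_sensitivity": metrics["sensitivity"],
            "validation_specificity": metrics["specificity"],
        }
    )
    settings_path = outdir / "settings.json"
    settings_path.write_text(
        json.dumps(
            {
                "alpha": config.alpha,
                "m_comparisons": config.m_comparisons,
                "glcm_distance": config.glcm_distance,
                "glcm_levels": config.glcm_levels,
                "correlation_variant": config.correlation_variant,
                "python": platform.python_version(),
            },
            indent=2,
            sort_keys=True,
        )
        + "\n"
    )
    report.outputs["settings"] = str(settings_path)
    report_path = outdir / "run_report.json"
    report_path.write_text(report.to_json() + "\n")
    report.outputs["run_report"] = str(report_path)
    return report
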