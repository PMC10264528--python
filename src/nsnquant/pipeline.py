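"""End-to-end drivers: per-nodule growth work-up and cohort analysis.

``run_nodule`` takes a baseline and a follow-up scan with their ROIs,
segments at the configured threshold, extracts the 12 features at both
timepoints, computes the LMD doubling time and assigns the risk flag:
``high`` when baseline skewness exceeds the skewness cutoff, escalating to
``highest`` when the baseline LMD also exceeds the LMD cutoff.

``run_cohort`` reproduces the cohort statistics chain on a feature table:
feature-vs-doubling-time correlations, growing-vs-nongrowing contrasts,
univariate and backward-stepwise multivariable logistic regression, and
ROC analyses (single predictors and the fitted multivariable model), all
emitted as machine-readable CSV plus a markdown report.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig
from .features import FeatureVector, extract_features
from .growth import GrowthResult, classify_growth, doubling_time_from_lmd
from .image import HUImage
from .segmentation import ROIPolygon, rasterize_roi, threshold_segment
from .stats import (LogisticModel, ROCResult, associate_features,
                    backward_stepwise, logistic_fit, roc_analysis)

logger = logging.getLogger(__name__)

#: The 12 features carried into the statistics stage (Feret is the mean of
#: the maximum and minimum caliper diameters).
ANALYSIS_FEATURES = (
    "feret_mean", "perimeter", "area", "mean_hu", "median_hu", "mode_hu",
    "sd_hu", "lmd", "skewness", "kurtosis", "circularity", "solidity",
)

DEFAULT_COVARIATES = ("age", "male", "smoker", "cancer_history",
                      "emphysema", "upper_lobe")

RISK_NONE = "none"
RISK_HIGH = "high"
RISK_HIGHEST = "highest"


@dataclass(frozen=True)
class NoduleReport:
    baseline: FeatureVector
    followup: FeatureVector
    growth: GrowthResult
    risk_flag: str


def risk_flag(baseline: FeatureVector, config: RunConfig) -> str:
    """Growth-risk flag from baseline skewness and LMD cutoffs."""
    if baseline.skewness > config.skewness_cutoff:
        if baseline.lmd > config.lmd_cutoff:
            return RISK_HIGHEST
        return RISK_HIGH
    return RISK_NONE


def analyze_timepoint(image: HUImage, roi: ROIPolygon,
                      config: RunConfig) -> FeatureVector:
    grid = rasterize_roi(roi, image.shape)
    mask = threshold_segment(image, grid, threshold=config.threshold_hu)
    return extract_features(image, mask)


def run_nodule(baseline: HUImage, followup: HUImage,
               roi_baseline: ROIPolygon, roi_followup: ROIPolygon,
               interval_days: float,
               config: RunConfig = RunConfig()) -> NoduleReport:
    """Full two-timepoint work-up of one nodule.

    Raises :class:`SegmentationError` with the observed HU range when a
    timepoint is not segmentable at the configured threshold.
    """
    feats_b = analyze_timepoint(baseline, roi_baseline, config)
    feats_f = analyze_timepoint(followup, roi_followup, config)
    dt = doubling_time_from_lmd(feats_b.lmd, feats_f.lmd, interval_days)
    growth = GrowthResult(
        interval=float(interval_days), lmd_ratio=feats_f.lmd / feats_b.lmd,
        doubling_time=dt, label=classify_growth(dt, config.dt_cutoff_days),
        cutoff_used=config.dt_cutoff_days)
    return NoduleReport(baseline=feats_b, followup=feats_f, growth=growth,
                        risk_flag=risk_flag(feats_b, config))


def nodule_report_frame(report: NoduleReport) -> pd.DataFrame:
    """Flatten a nodule report for CSV output."""
    rows = []
    for tp, feats in (("baseline", report.baseline),
                      ("followup", report.followup)):
        row = {"timepoint": tp, **feats.as_dict(),
               "flags": ";".join(feats.flags)}
        rows.append(row)
    frame = pd.DataFrame(rows)
    frame["doubling_time"] = report.growth.doubling_time
    frame["growth_label"] = report.growth.label
    frame["risk_flag"] = report.risk_flag
    return frame


# --------------------------------------------------------------------------
# cohort analysis

@dataclass(frozen=True)
class CohortReport:
    associations: pd.DataFrame        # correlations + group contrasts
    univariate: pd.DataFrame          # per-variable OR / beta / p
    multivariable: LogisticModel
    multivariable_table: pd.DataFrame
    roc: dict[str, ROCResult]         # per score: raw predictors + model
    config: RunConfig


def _univariate_table(table: pd.DataFrame, variables: list[str],
                      outcome: np.ndarray) -> pd.DataFrame:
    rows = []
    for name in variables:
        model = logistic_fit(table[[name]], outcome)
        beta = model.coefficient(name)
        rows.append({
            "variable": name,
            "odds_ratio": float(np.exp(beta)),
            "beta": beta,
            "p_value": model.p_value(name),
            "separation": model.separation,
        })
    return pd.DataFrame(rows).set_index("variable")


def run_cohort(table: pd.DataFrame, config: RunConfig = RunConfig(),
               covariates: tuple[str, ...] | None = None) -> CohortReport:
    """Cohort-level statistics on a feature table.

    ``table`` needs the 12 feature columns, a binary ``growing`` outcome, a
    ``doubling_time`` column (may contain ``inf`` for stable nodules) and
    any covariate columns.
    """
    features = [f for f in ANALYSIS_FEATURES if f in table.columns]
    if covariates is None:
        covariates = tuple(c for c in DEFAULT_COVARIATES if c in table.columns)
    if "growing" not in table.columns:
        raise ValueError("table must contain a binary 'growing' outcome column")
    outcome = table["growing"].to_numpy(int)

    assoc = associate_features(table, features)
    assoc_frame = pd.DataFrame([{
        "variable": a.variable,
        "spearman_rho": a.spearman_rho, "spearman_p": a.spearman_p,
        "median_growing": a.median_growing,
        "iqr25_growing": a.iqr_growing[0], "iqr75_growing": a.iqr_growing[1],
        "median_nongrowing": a.median_nongrowing,
        "iqr25_nongrowing": a.iqr_nongrowing[0],
        "iqr75_nongrowing": a.iqr_nongrowing[1],
        "u_statistic": a.u_statistic, "mann_whitney_p": a.mann_whitney_p,
    } for a in assoc]).set_index("variable")

    variables = features + list(covariates)
    uni = _univariate_table(table, variables, outcome)
    model = backward_stepwise(table[variables], outcome,
                              p_enter=config.p_enter,
                              p_remove=config.p_remove)
    multi_rows = [{
        "variable": name,
        "odds_ratio": model.odds_ratios[name],
        "beta": model.coefficient(name),
        "p_value": model.p_value(name),
    } for name in model.predictors]
    multi_frame = (pd.DataFrame(multi_rows).set_index("variable")
                   if multi_rows else
                   pd.DataFrame(columns=["odds_ratio", "beta", "p_value"]))

    roc: dict[str, ROCResult] = {}
    for name in ("skewness", "lmd"):
        if name in table.columns:
            roc[name] = roc_analysis(table[name].to_numpy(float), outcome)
    if model.predictors:
        proba = model.predict_proba(table)
        roc["multivariable_model"] = roc_analysis(proba, outcome)
    return CohortReport(associations=assoc_frame, univariate=uni,
                        multivariable=model, multivariable_table=multi_frame,
                        roc=roc, config=config)


# --------------------------------------------------------------------------
# report output

_FLOAT_FMT = "%.6g"


def write_cohort_report(report: CohortReport, out_dir: str | Path) -> Path:
    """Write the cohort tables as CSV plus a markdown summary.

    Output is byte-deterministic for a given table and configuration.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.associations.to_csv(out / "associations.csv",
                               float_format=_FLOAT_FMT)
    report.univariate.to_csv(out / "univariate_logistic.csv",
                             float_format=_FLOAT_FMT)
    report.multivariable_table.to_csv(out / "multivariable_logistic.csv",
                                      float_format=_FLOAT_FMT)
    for name, roc in report.roc.items():
        pd.DataFrame({
            "threshold": roc.thresholds,
            "sensitivity": roc.sensitivity,
            "specificity": roc.specificity,
        }).to_csv(out / f"roc_{name}.csv", index=False,
                  float_format=_FLOAT_FMT)

    lines = ["# Cohort analysis report", ""]
    cfg = report.config
    lines += [
        "## Provenance",
        "",
        f"- nsnquant version: {__version__}",
        f"- segmentation threshold: {cfg.threshold_hu:g} HU (inclusive)",
        f"- doubling-time cutoff: {cfg.dt_cutoff_days:g} days",
        f"- risk cutoffs: skewness > {cfg.skewness_cutoff:g}, "
        f"LMD > {cfg.lmd_cutoff:g} mg/mm",
        f"- stepwise: entry p < {cfg.p_enter:g}, removal p > {cfg.p_remove:g}",
        f"- seed: {cfg.seed}",
        "",
        "## Multivariable model (backward stepwise)",
        "",
    ]
    if report.multivariable.predictors:
        lines.append("| variable | OR | beta | p |")
        lines.append("|---|---|---|---|")
        for name in report.multivariable.predictors:
            m = report.multivariable
            lines.append(
                f"| {name} | {m.odds_ratios[name]:.4g} | "
                f"{m.coefficient(name):.4g} | {m.p_value(name):.4g} |")
    else:
        lines.append("No predictor survived backward elimination "
                     "(intercept-only model).")
    if report.multivariable.elimination_trace:
        lines += ["", "Elimination order: "
                  + ", ".join(report.multivariable.elimination_trace)]
    lines += ["", "## ROC analyses", ""]
    lines.append("| score | AUC | optimal cutoff | Youden J |")
    lines.append("|---|---|---|---|")
    for name, roc in report.roc.items():
        lines.append(f"| {name} | {roc.auc:.4g} | {roc.optimal_cutoff:.4g} | "
                     f"{roc.youden_j:.4g} |")
    lines.append("")
    path = out / "report.md"
    path.write_text("\n".join(lines))
    return path
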