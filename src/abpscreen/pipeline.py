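"""End-to-end analysis: ingest -> QC -> summarize -> phenotype -> report.

Produces a deterministic report bundle with a subject-flow ledger,
per-threshold validity tables, agreement and correlation blocks, stratified
tables, the covariate regression on device differences, and the two
sensitivity analyses (include medicated subjects; include quality-failing
records).
"""

from __future__ import annotations

import json
import logging
import math
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator

from . import core, phenotype as ph, stats

logger = logging.getLogger(__name__)

BMI_BINS = (18.5, 25.0, 30.0)
BMI_LABELS = ("underweight", "normal", "overweight", "obese")
AGE_BANDS = ((18, 30), (30, 40), (40, 50), (50, 60), (60, 70), (70, 200))

KNOWN_STRATA = ("sex", "age_group", "site", "bmi_category")


class AnalysisConfig(BaseModel):
    """Run-time options for the validation analysis."""

    thresholds: list[str] = Field(default=list(ph.DEFAULT_THRESHOLDS), min_length=1)
    reference: str = "24h"
    exclude_medicated: bool = True
    include_qc_failures: bool = False
    strata: list[str] = Field(default_factory=list)
    ci_method: str = "wilson"
    weighting_mode: str = "interval"
    dipping_ratio_cut: float = Field(default=0.9, gt=0)
    seed: int = 0

    @field_validator("reference")
    @classmethod
    def _ref(cls, v: str) -> str:
        if v not in ("24h", "daytime"):
            raise ValueError("reference must be '24h' or 'daytime'")
        return v

    @field_validator("strata")
    @classmethod
    def _strata(cls, v: list[str]) -> list[str]:
        bad = [s for s in v if s not in KNOWN_STRATA]
        if bad:
            raise ValueError(f"unknown strata {bad}; known: {KNOWN_STRATA}")
        return v

    @field_validator("ci_method")
    @classmethod
    def _ci(cls, v: str) -> str:
        if v not in ("wilson", "exact", "wald"):
            raise ValueError("ci_method must be wilson, exact, or wald")
        return v


def prevalence_percent(n_confirmed: int, n_analyzed: int) -> int:
    """Reported prevalence line: integer percent of confirmed hypertensives."""
    if n_analyzed < 1:
        raise ValueError("n_analyzed must be >= 1")
    return int(round(100.0 * n_confirmed / n_analyzed))


def bmi_category(bmi: float) -> str:
    if math.isnan(bmi):
        return "missing"
    idx = int(np.searchsorted(BMI_BINS, bmi, side="right"))
    return BMI_LABELS[idx]


def age_group(age: float) -> str:
    if math.isnan(age):
        return "missing"
    for lo, hi in AGE_BANDS:
        if lo <= age < hi:
            return f"{lo}-{hi - 1}" if hi < 200 else f"{lo}+"
    return "missing"


def stratify(subjects: pd.DataFrame, key: str) -> dict[str, pd.DataFrame]:
    """Disjoint, exhaustive partition of an analysis set by a stratum key.

    Missing covariates land in an explicit ``missing`` stratum.
    """
    if key not in KNOWN_STRATA:
        raise ValueError(f"unknown stratum key {key!r}")
    df = subjects.copy()
    if key == "bmi_category":
        labels = df["bmi"].astype(float).map(bmi_category)
    elif key == "age_group":
        labels = df["age"].astype(float).map(age_group)
    else:
        labels = df[key].fillna("missing").astype(str)
    return {str(lab): df[labels == lab] for lab in sorted(labels.unique())}


def _estimate_block(mx: dict[str, stats.MetricEstimate]) -> dict:
    return {name: est.as_dict() for name, est in mx.items()}


def _validity_block(table: stats.ConfusionTable, ci_method: str) -> dict:
    block: dict = {
        "confusion": {"tp": table.tp, "fp": table.fp, "fn": table.fn, "tn": table.tn},
        "n": table.total,
    }
    block.update(_estimate_block(stats.validity_metrics(table, ci_method)))
    block.update(_estimate_block(stats.likelihood_ratios(table)))
    try:
        block["auc_binary"] = stats.auc_point(table)
    except ValueError:
        block["auc_binary"] = None
    return block


def _phenotype_frame(
    analysis: pd.DataFrame, config: AnalysisConfig
) -> pd.DataFrame:
    """Per-subject screen/reference/phenotype labels at every threshold."""
    rows = []
    for thr_label in config.thresholds:
        thr = ph.ThresholdPair.parse(thr_label)
        for _, row in analysis.iterrows():
            screen = ph.screen_status(row["office_sbp"], row["office_dbp"], thr)
            confirmed_24h = row["wt24_sbp"] >= 130.0 or row["wt24_dbp"] >= 80.0
            confirmed_day = row["day_sbp"] >= 135.0 or row["day_dbp"] >= 85.0
            nocturnal = row["night_sbp"] >= 120.0 or row["night_dbp"] >= 70.0
            confirmed = confirmed_24h if config.reference == "24h" else confirmed_day
            ratio = row["night_sbp"] / row["day_sbp"] if row["day_sbp"] else math.nan
            rows.append(
                {
                    "subject_id": row["subject_id"],
                    "threshold_label": thr_label,
                    "screen_positive": screen,
                    "confirmed_24h": confirmed_24h,
                    "confirmed_daytime": confirmed_day,
                    "nocturnal_htn": nocturnal,
                    "phenotype": ph.phenotype(screen, confirmed),
                    "dipping": (
                        "nondipper"
                        if ratio > config.dipping_ratio_cut
                        else ("dipper" if not math.isnan(ratio) else "missing")
                    ),
                }
            )
    return pd.DataFrame(rows)


def _reference_flags(analysis: pd.DataFrame, reference: str) -> pd.Series:
    if reference == "24h":
        return (analysis["wt24_sbp"] >= 130.0) | (analysis["wt24_dbp"] >= 80.0)
    return (analysis["day_sbp"] >= 135.0) | (analysis["day_dbp"] >= 85.0)


def _screen_flags(analysis: pd.DataFrame, thr: ph.ThresholdPair) -> pd.Series:
    return (analysis["office_sbp"] >= thr.sbp_cut) | (analysis["office_dbp"] >= thr.dbp_cut)


def _analysis_report(analysis: pd.DataFrame, config: AnalysisConfig) -> dict:
    """Validity, agreement and stratified blocks on one analysis set."""
    report: dict = {}
    reference = _reference_flags(analysis, config.reference)
    n = len(analysis)
    n_conf = int(reference.sum())
    report["n_analyzed"] = n
    report["n_confirmed"] = n_conf
    report["prevalence_percent"] = prevalence_percent(n_conf, n) if n else None

    thresholds: dict = {}
    for thr_label in config.thresholds:
        thr = ph.ThresholdPair.parse(thr_label)
        screen = _screen_flags(analysis, thr)
        table = stats.confusion_table(screen.to_numpy(), reference.to_numpy())
        block = _validity_block(table, config.ci_method)
        block["screen_positive_percent"] = (
            round(100.0 * float(screen.mean()), 1) if n else None
        )
        counts = {
            "sustained": table.tp,
            "white_coat": table.fp,
            "masked": table.fn,
            "normotensive": table.tn,
        }
        block["phenotype_counts"] = counts
        thresholds[thr_label] = block
    report["thresholds"] = thresholds

    # continuous-score AUROC: office systolic mean as the score
    if n and reference.nunique() == 2:
        report["auc_empirical_sbp"] = stats.auc_empirical(
            analysis["office_sbp"].to_numpy(), reference.to_numpy()
        ).as_dict()
    else:
        report["auc_empirical_sbp"] = None

    # agreement and correlation of office vs ambulatory measures
    agreement: dict = {}
    for label, abp_col in (("24h", "wt24"), ("daytime", "day")):
        for comp in ("sbp", "dbp"):
            pair = analysis[[f"office_{comp}", f"{abp_col}_{comp}"]].dropna()
            key = f"office_vs_{label}_{comp}"
            if len(pair) >= 3:
                ba = stats.bland_altman(
                    pair[f"office_{comp}"].to_numpy(), pair[f"{abp_col}_{comp}"].to_numpy()
                )
                corr = stats.pearson_correlation(
                    pair[f"office_{comp}"].to_numpy(), pair[f"{abp_col}_{comp}"].to_numpy()
                )
                agreement[key] = {"bland_altman": ba.as_dict(), "correlation": corr}
            else:
                agreement[key] = None
    report["agreement"] = agreement

    # stratified validity tables
    strata_block: dict = {}
    for key in config.strata:
        parts = stratify(analysis, key)
        per_level: dict = {}
        for level, sub in parts.items():
            ref_s = _reference_flags(sub, config.reference)
            level_block: dict = {"n": len(sub)}
            for thr_label in config.thresholds:
                thr = ph.ThresholdPair.parse(thr_label)
                table = stats.confusion_table(
                    _screen_flags(sub, thr).to_numpy(), ref_s.to_numpy()
                )
                level_block[thr_label] = _validity_block(table, config.ci_method)
            per_level[level] = level_block
        strata_block[key] = per_level
    report["strata"] = strata_block

    # covariate regression on the office-minus-24h difference
    regression: dict = {}
    covs = ["age", "sex", "site", "bmi", "diabetes", "smoker"]
    if n >= 20 and all(c in analysis.columns for c in covs):
        for comp in ("sbp", "dbp"):
            df = analysis.copy()
            df["diff"] = df[f"office_{comp}"] - df[f"wt24_{comp}"]
            try:
                coefs = stats.difference_regression(
                    df, "diff", covs, categorical=("sex", "site")
                )
                regression[comp] = {
                    term: {
                        "coef": float(r["coef"]),
                        "se": float(r["se"]),
                        "p_value": float(r["p_value"]),
                    }
                    for term, r in coefs.iterrows()
                }
            except ValueError as exc:
                regression[comp] = {"error": str(exc)}
    report["difference_regression"] = regression
    return report


def build_analysis_frame(
    summaries: pd.DataFrame,
    office: pd.DataFrame,
    subjects: pd.DataFrame,
) -> pd.DataFrame:
    """Join summaries, office means and covariates on subject_id."""
    df = summaries.merge(office, on="subject_id", how="outer")
    df = df.merge(subjects, on="subject_id", how="outer")
    return df


def run_pipeline(
    readings_path,
    office_path,
    subjects_path,
    config: Optional[AnalysisConfig] = None,
) -> dict:
    """Run the full analysis from raw files; identical inputs give identical output."""
    config = config or AnalysisConfig()
    records = core.parse_readings(readings_path)
    summaries = core.summarize_records(records, config.weighting_mode)
    sessions, office_excluded = core.parse_office(office_path)
    office = core.office_means_frame(sessions)
    subjects = pd.read_csv(subjects_path)
    if "on_medication" not in subjects.columns:
        subjects["on_medication"] = 0
    return run_analysis(summaries, office, subjects, config,
                        n_office_excluded=len(office_excluded))


def run_analysis(
    summaries: pd.DataFrame,
    office: pd.DataFrame,
    subjects: pd.DataFrame,
    config: Optional[AnalysisConfig] = None,
    n_office_excluded: int = 0,
) -> dict:
    """Analysis and report from already-summarised inputs."""
    config = config or AnalysisConfig()
    merged = build_analysis_frame(summaries, office, subjects)
    n_parsed = len(merged)

    has_abpm = merged["qc_pass"].notna()
    qc_pass = merged["qc_pass"].fillna(False).astype(bool)
    has_office = merged["office_sbp"].notna()
    medicated = merged["on_medication"].fillna(0).astype(int).astype(bool)

    usable_abpm = qc_pass | (
        bool(config.include_qc_failures) & has_abpm & merged["wt24_sbp"].notna()
    )
    # each subject lands in exactly one terminal bin, tested first-fail-wins
    bins = pd.Series("analyzed", index=merged.index)
    bins[~has_abpm | ~usable_abpm] = "qc_fail"
    bins[(bins == "analyzed") & ~has_office] = "insufficient_office"
    if config.exclude_medicated:
        bins[(bins == "analyzed") & medicated] = "medicated_excluded"

    for _, row in merged[bins != "analyzed"].iterrows():
        logger.info(
            "excluded subject %s: reason=%s", row["subject_id"], bins[row.name]
        )

    analysis = merged[bins == "analyzed"].reset_index(drop=True)

    flow = {
        "n_parsed": n_parsed,
        "n_with_abpm": int(has_abpm.sum()),
        "n_qc_fail": int((bins == "qc_fail").sum()),
        "n_insufficient_office": int((bins == "insufficient_office").sum())
        + n_office_excluded,
        "n_medicated_excluded": int((bins == "medicated_excluded").sum()),
        "n_analyzed": int((bins == "analyzed").sum()),
    }

    report = {
        "config": config.model_dump(),
        "flow": flow,
    }
    report.update(_analysis_report(analysis, config))
    report["phenotypes"] = _phenotype_frame(analysis, config).to_dict(orient="records")
    return report


def sensitivity_analyses(
    summaries: pd.DataFrame,
    office: pd.DataFrame,
    subjects: pd.DataFrame,
    config: Optional[AnalysisConfig] = None,
) -> dict:
    """Re-run with medicated subjects and QC-failing records included.

    Returns the base report plus per-toggle metric deltas (sensitivity and
    specificity at each threshold, against the base run).
    """
    config = config or AnalysisConfig()
    base = run_analysis(summaries, office, subjects, config)

    def _deltas(alt: dict) -> dict:
        out = {}
        for thr, block in alt["thresholds"].items():
            base_block = base["thresholds"][thr]
            out[thr] = {
                "n_delta": block["n"] - base_block["n"],
                "sensitivity_delta": _est_delta(block, base_block, "sensitivity"),
                "specificity_delta": _est_delta(block, base_block, "specificity"),
            }
        return out

    variants = {}
    med_cfg = config.model_copy(update={"exclude_medicated": False})
    med = run_analysis(summaries, office, subjects, med_cfg)
    variants["include_medicated"] = {"report": med, "deltas": _deltas(med)}

    qc_cfg = config.model_copy(update={"include_qc_failures": True})
    qc = run_analysis(summaries, office, subjects, qc_cfg)
    variants["include_qc_failures"] = {"report": qc, "deltas": _deltas(qc)}

    return {"base": base, "variants": variants}


def _est_delta(block: dict, base_block: dict, name: str) -> Optional[float]:
    a, b = block.get(name), base_block.get(name)
    if not a or not b:
        return None
    if a["estimate"] is None or b["estimate"] is None:
        return None
    if math.isnan(a["estimate"]) or math.isnan(b["estimate"]):
        return None
    return a["estimate"] - b["estimate"]


def report_to_json(report: dict, path=None) -> str:
    """Deterministic JSON rendering (sorted keys, NaN-safe)."""
    text = json.dumps(_sanitize(report), indent=2, sort_keys=True)
    if path is not None:
        Path(path).write_text(text + "\n")
    return text


def _sanitize(obj):
    if isinstance(obj, dict):
        return {str(k): _sanitize(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_sanitize(v) for v in obj]
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        obj = float(obj)
    if isinstance(obj, float):
        if math.isnan(obj):
            return None
        if math.isinf(obj):
            return "inf" if obj > 0 else "-inf"
    return obj


def validity_tables_csv(report: dict, path=None) -> pd.DataFrame:
    """Flatten the per-threshold validity blocks to a tidy table."""
    rows = []
    for thr, block in report["thresholds"].items():
        for metric in ("sensitivity", "specificity", "ppv", "npv", "lr_pos", "lr_neg"):
            est = block.get(metric)
            if not est:
                continue
            rows.append(
                {
                    "threshold": thr,
                    "metric": metric,
                    "estimate": est["estimate"],
                    "ci_low": est["ci_low"],
                    "ci_high": est["ci_high"],
                    "ci_method": est["ci_method"],
                    "n": est["n"],
                }
            )
        rows.append(
            {
                "threshold": thr,
                "metric": "auc_binary",
                "estimate": block["auc_binary"],
                "ci_low": None,
                "ci_high": None,
                "ci_method": None,
                "n": block["n"],
            }
        )
    df = pd.DataFrame(rows)
    if path is not None:
        df.to_csv(path, index=False)
    return df
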