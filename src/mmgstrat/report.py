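"""End-to-end pipeline orchestration and report emission.

``run_full_analysis`` chains ingest -> validation -> metrics -> inference
-> cross-validation -> stratification and writes the bundle: metrics.csv,
analysis.json, crossval.json, strata.csv, cutpoints.csv, and a
human-readable summary.txt.  The JSON files are the machine-readable
source of truth (full precision, method labels, seeds echoed); the text
tables are derived, display-rounded views — no statistic is computed in
the formatting layer.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import crossval as cv
from . import inference as inf
from .stratify import (
    OUTCOME_NAMES,
    StratumSummary,
    TE_DEFAULT,
    TRR_DEFAULT,
    cutpoint_scan,
    plateau_check,
    stratify as stratify_metrics,
)
from .cohort import Cohort, MetricConfig, read_cohort, validate_cohort
from .metrics import compute_metrics, nerve_level_summary

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    nerves_csv: str
    patients_csv: str
    out_dir: str
    metric: MetricConfig = MetricConfig()
    seed: int = 17
    bootstrap_reps: int = 2000
    kfold_k: int = 5
    run_steiger: bool = True


# ---------------------------------------------------------------------------
# display formatting (display only -- never feeds back into statistics)

def fmt_pct(x: float, decimals: int = 1) -> str:
    """Fraction -> percentage string, e.g. 0.7647 -> '76.5%'."""
    return f"{100 * x:.{decimals}f}%"


def fmt_pct_ci(lo: float, hi: float) -> str:
    """CI of a fraction, truncated to [0, 100]% for display; exact
    boundaries print without a decimal ('100%', not '100.0%')."""

    def one(v: float) -> str:
        v = min(max(v, 0.0), 1.0)
        return "0" if v == 0.0 else "100" if v == 1.0 else f"{100 * v:.1f}"

    return f"({one(lo)}-{one(hi)}%)"


def fmt_r(x: float) -> str:
    return f"{x:.3f}"


def fmt_ma(x: float) -> str:
    return f"{x:.2f}"


def format_table(rows: list[list[str]], headers: list[str]) -> str:
    """Fixed-width text table from pre-formatted cells."""
    table = [headers] + rows
    widths = [max(len(r[i]) for r in table) for i in range(len(headers))]
    lines = []
    for j, r in enumerate(table):
        lines.append("  ".join(c.ljust(w) for c, w in zip(r, widths)).rstrip())
        if j == 0:
            lines.append("  ".join("-" * w for w in widths))
    return "\n".join(lines)


def _corr_block(result: inf.CorrelationResult) -> dict:
    return {
        "r": result.r,
        "ci95": [result.ci_lo, result.ci_hi],
        "p": result.p,
        "n": result.n,
        "method": "pearson, fisher-z CI, t-test",
    }


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and math.isnan(obj):
        return None
    return obj


def analyze_metrics(
    metrics_df: pd.DataFrame,
    reference_mA: float = 2.0,
    bootstrap_reps: int = 2000,
    seed: int = 17,
    run_steiger: bool = True,
) -> dict:
    """Inference block: correlations, dependent-correlation comparison,
    dose-response (linear + logistic), contingency at the reference cutoff,
    and the sufficiency-plateau check.

    Correlations being compared by the Steiger test are computed on the
    identical matched subset (defined TRR and baseline pain) for parity.
    """
    pain = metrics_df.dropna(subset=["pain_improvement_frac"])
    matched = pain.dropna(subset=["trr"])
    imp = pain["pain_improvement_frac"].to_numpy(dtype=float)

    out: dict = {
        "n_pain": int(len(pain)),
        "n_matched": int(len(matched)),
        "seed": seed,
        "correlations": {},
    }
    out["correlations"]["pct_change"] = _corr_block(
        inf.pearson_with_ci(pain["pct_change"].to_numpy(dtype=float), imp)
    )
    out["correlations"]["te"] = _corr_block(
        inf.pearson_with_ci(pain["te"].to_numpy(dtype=float), imp)
    )
    m_imp = matched["pain_improvement_frac"].to_numpy(dtype=float)
    trr_m = inf.pearson_with_ci(matched["trr"].to_numpy(dtype=float), m_imp)
    pct_m = inf.pearson_with_ci(matched["pct_change"].to_numpy(dtype=float), m_imp)
    out["correlations"]["trr"] = _corr_block(trr_m)
    out["correlations"]["pct_change_matched"] = _corr_block(pct_m)

    if run_steiger and len(matched) >= 4:
        r12 = float(
            np.corrcoef(
                matched["trr"].to_numpy(dtype=float),
                matched["pct_change"].to_numpy(dtype=float),
            )[0, 1]
        )
        z, p = inf.steiger_test(trr_m.r, pct_m.r, r12, len(matched))
        out["steiger"] = {
            "r_trr": trr_m.r, "r_pct": pct_m.r, "r_between": r12,
            "n": int(len(matched)), "z": z, "p": p,
            "method": "Steiger (1980) Z, averaged-correlation covariance",
        }

    te_fit = inf.ols_fit(
        imp, pd.DataFrame({"te": pain["te"].to_numpy(dtype=float)})
    )
    out["dose_response"] = {
        "linear_te": _jsonable(te_fit) | {"method": "OLS, t-based CI"},
        "adjusted_trr": _jsonable(inf.adjusted_trr_model(metrics_df))
        | {"method": "OLS: improvement ~ trr + nps_pre + n_nerves + region"},
    }
    try:
        logit = inf.logistic_fit(
            pain["complete_relief"].to_numpy(dtype=bool),
            pain["te"].to_numpy(dtype=float),
            bootstrap_reps=bootstrap_reps,
            seed=seed,
        )
        out["dose_response"]["logistic_te"] = _jsonable(logit) | {
            "method": "logistic MLE; Wald CI; percentile bootstrap CI"
        }
    except inf.InferenceError as exc:
        out["dose_response"]["logistic_te"] = {"error": str(exc)}

    achieved = pain["te"].to_numpy(dtype=float) <= 0.0
    relief = pain["complete_relief"].to_numpy(dtype=bool)
    try:
        tbl = inf.odds_ratio_2x2(
            int((achieved & relief).sum()), int((achieved & ~relief).sum()),
            int((~achieved & relief).sum()), int((~achieved & ~relief).sum()),
        )
        out["contingency_reference"] = _jsonable(tbl) | {
            "cutoff_mA": reference_mA,
            "method": "odds ratio; two-sided Fisher exact p (probability-mass summation)",
        }
    except inf.InferenceError as exc:
        out["contingency_reference"] = {"error": str(exc)}

    try:
        out["plateau_below_reference"] = _corr_block(
            plateau_check(metrics_df, reference_mA)
        )
    except inf.InsufficientDataError as exc:
        out["plateau_below_reference"] = {"error": str(exc)}
    return out


def crossval_metrics(metrics_df: pd.DataFrame, kfold_k: int = 5, seed: int = 17) -> dict:
    """LOOCV comparison of the three metrics plus a seeded k-fold replicate."""
    loo = cv.compare_metrics_cv(metrics_df)
    out = {"seed": seed, "k": kfold_k, "loocv": [], "kfold": []}
    for r in loo:
        d = _jsonable(r)
        out["loocv"].append(d)
    for r in loo:
        df = metrics_df.dropna(subset=[r.metric_name, "pain_improvement_frac"])
        kf = cv.kfold_linear(
            df[r.metric_name].to_numpy(dtype=float),
            df["pain_improvement_frac"].to_numpy(dtype=float),
            k=min(kfold_k, len(df)),
            seed=seed,
            metric_name=r.metric_name,
        )
        out["kfold"].append(_jsonable(kf))
    return out


def _strata_frame(summaries: list[StratumSummary], metric_name: str) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "metric": metric_name,
            "label": [s.label for s in summaries],
            "n": [s.n for s in summaries],
            "mean_improvement": [s.mean_improvement for s in summaries],
            "improvement_ci_lo": [s.improvement_ci[0] for s in summaries],
            "improvement_ci_hi": [s.improvement_ci[1] for s in summaries],
            "relief_rate": [s.relief_rate.point for s in summaries],
            "relief_ci_lo": [s.relief_rate.lo for s in summaries],
            "relief_ci_hi": [s.relief_rate.hi for s in summaries],
        }
    )


def run_full_analysis(run_config: RunConfig) -> dict:
    """Execute the whole pipeline and write the report bundle.

    Returns the in-memory bundle: ``{"metrics": DataFrame, "analysis":
    dict, "crossval": dict, "strata": DataFrame, "cutpoints": DataFrame,
    "summary": str}``.  Exclusions (zero baseline pain, undefined TRR) are
    logged with patient ids.
    """
    out_dir = Path(run_config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cohort = read_cohort(run_config.nerves_csv, run_config.patients_csv)
    anomalies = validate_cohort(cohort, run_config.metric.reference_mA)
    for a in anomalies:
        log.warning("anomaly [%s] patient %s: %s", a.kind, a.patient_id, a.detail)

    metrics_df = compute_metrics(cohort, run_config.metric)
    zero_baseline = metrics_df.loc[
        metrics_df["pain_improvement_frac"].isna(), "patient_id"
    ].tolist()
    no_trr = metrics_df.loc[metrics_df["trr"].isna(), "patient_id"].tolist()
    if zero_baseline:
        log.info("excluded from pain analyses (zero baseline): %s", zero_baseline)
    if no_trr:
        log.info("excluded from TRR analyses (no baseline elevation): %s", no_trr)

    analysis = analyze_metrics(
        metrics_df,
        reference_mA=run_config.metric.reference_mA,
        bootstrap_reps=run_config.bootstrap_reps,
        seed=run_config.seed,
        run_steiger=run_config.run_steiger,
    )
    analysis["provenance"] = dict(cohort.provenance)
    analysis["anomalies"] = [_jsonable(a) for a in anomalies]
    analysis["exclusions"] = {
        "zero_baseline": zero_baseline,
        "undefined_trr": no_trr,
    }
    crossval = crossval_metrics(metrics_df, run_config.kfold_k, run_config.seed)

    trr_defined = metrics_df.dropna(subset=["trr"])
    strata = pd.concat(
        [
            _strata_frame(stratify_metrics(trr_defined, TRR_DEFAULT), "trr"),
            _strata_frame(stratify_metrics(metrics_df, TE_DEFAULT), "te"),
        ],
        ignore_index=True,
    )

    cut_frames = []
    for outcome in OUTCOME_NAMES:
        try:
            scan = cutpoint_scan(
                metrics_df, outcome, reference_mA=run_config.metric.reference_mA
            )
        except inf.DegenerateOutcomeError as exc:
            log.warning("cutpoint scan skipped for %s: %s", outcome, exc)
            continue
        f = pd.DataFrame([_jsonable(r) for r in scan.results])
        f["auc"] = scan.auc
        cut_frames.append(f)
    cutpoints = (
        pd.concat(cut_frames, ignore_index=True) if cut_frames else pd.DataFrame()
    )

    summary = _summary_text(cohort, metrics_df, analysis, crossval, strata, run_config)

    metrics_df.to_csv(out_dir / "metrics.csv", index=False)
    (out_dir / "analysis.json").write_text(
        json.dumps(_jsonable(analysis), indent=2, sort_keys=True, allow_nan=False)
    )
    (out_dir / "crossval.json").write_text(
        json.dumps(_jsonable(crossval), indent=2, sort_keys=True, allow_nan=False)
    )
    strata.to_csv(out_dir / "strata.csv", index=False)
    cutpoints.to_csv(out_dir / "cutpoints.csv", index=False)
    (out_dir / "summary.txt").write_text(summary)
    return {
        "metrics": metrics_df,
        "analysis": analysis,
        "crossval": crossval,
        "strata": strata,
        "cutpoints": cutpoints,
        "summary": summary,
    }


def _summary_text(
    cohort: Cohort,
    metrics_df: pd.DataFrame,
    analysis: dict,
    crossval: dict,
    strata: pd.DataFrame,
    run_config: RunConfig,
) -> str:
    nsum = nerve_level_summary(cohort, run_config.metric)
    lines = []
    lines.append("Cohort")
    lines.append(
        f"  patients: {cohort.n_patients}  nerves: {cohort.n_nerves}  "
        f"pain analyses n={analysis['n_pain']}  TRR analyses n={analysis['n_matched']}"
    )
    lines.append(
        f"  nerve-level: elevated {nsum.n_elevated}/{nsum.n_nerves} "
        f"({fmt_pct(nsum.frac_elevated)}); improved >= "
        f"{run_config.metric.min_improvement_mA:g} mA: {nsum.n_improved}/{nsum.n_elevated}; "
        f"normalized: {nsum.n_normalized}/{max(nsum.n_improved, 1)}"
    )
    lines.append(
        f"  mean threshold {fmt_ma(nsum.mean_pre_mA)} -> {fmt_ma(nsum.mean_post_mA)} mA "
        f"(mean reduction {fmt_ma(nsum.mean_reduction_mA)} mA, "
        f"mean per-nerve reduction {fmt_pct(nsum.mean_pct_reduction)})"
    )
    lines.append("")
    lines.append("Correlations with pain improvement")
    rows = []
    for key, blk in analysis["correlations"].items():
        rows.append(
            [key, str(blk["n"]), fmt_r(blk["r"]),
             f"({fmt_r(blk['ci95'][0])}, {fmt_r(blk['ci95'][1])})",
             f"{blk['p']:.3g}"]
        )
    lines.append(format_table(rows, ["metric", "n", "r", "95% CI", "p"]))
    if "steiger" in analysis:
        sg = analysis["steiger"]
        lines.append(
            f"  dependent-correlation comparison (matched n={sg['n']}): "
            f"Z = {sg['z']:.2f}, p = {sg['p']:.3f}"
        )
    lines.append("")
    lin = analysis["dose_response"]["linear_te"]
    slope, lo, hi = lin["coefficients"][1], lin["ci_lo"][1], lin["ci_hi"][1]
    lines.append(
        f"Dose-response: improvement per mA of TE = {slope:.3f} "
        f"(95% CI {lo:.3f} to {hi:.3f}), R^2 = {lin['r_squared']:.3f}"
    )
    logit = analysis["dose_response"].get("logistic_te", {})
    if "or_per_unit" in logit:
        lines.append(
            f"  complete relief: OR per mA = {logit['or_per_unit']:.2f} "
            f"(Wald {logit['wald_ci_lo']:.2f}-{logit['wald_ci_hi']:.2f}; "
            f"bootstrap {logit['bootstrap_ci_lo']:.2f}-{logit['bootstrap_ci_hi']:.2f}; "
            f"seed {logit['bootstrap_seed']})"
        )
    if "odds_ratio" in analysis.get("contingency_reference", {}):
        ct = analysis["contingency_reference"]
        lines.append(
            f"  at/below reference vs above: OR = {ct['odds_ratio']:.1f}, "
            f"Fisher exact p = {ct['exact_p']:.3f}"
        )
    lines.append("")
    lines.append("Stratified outcomes")
    rows = [
        [r["metric"], r["label"], str(r["n"]),
         f"{fmt_pct(r['mean_improvement'])} "
         f"{fmt_pct_ci(r['improvement_ci_lo'], r['improvement_ci_hi'])}"
         if not math.isnan(r["mean_improvement"]) else "-",
         f"{fmt_pct(r['relief_rate'])} "
         f"{fmt_pct_ci(r['relief_ci_lo'], r['relief_ci_hi'])}"
         if not math.isnan(r["relief_rate"]) else "-"]
        for r in strata.to_dict("records")
    ]
    lines.append(
        format_table(rows, ["metric", "category", "n", "mean improvement (CI)",
                            "complete relief (Wilson CI)"])
    )
    lines.append("")
    lines.append("Cross-validation (LOOCV)")
    rows = [
        [r["metric_name"], str(r["n"]), fmt_r(r["apparent_r"]), fmt_r(r["cv_r"]),
         f"{r['shrinkage_pct']:.1f}%" if r["shrinkage_pct"] is not None else "-",
         f"{r['rmse']:.3f}", f"{r['loocv_beta']:.3f}"]
        for r in crossval["loocv"]
    ]
    lines.append(
        format_table(rows, ["metric", "n", "apparent r", "cv r", "shrinkage",
                            "RMSE", "mean held-out slope"])
    )
    lines.append("")
    lines.append(f"seed: {run_config.seed}  aggregation: {run_config.metric.aggregation}")
    return "\n".join(lines) + "\n"
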