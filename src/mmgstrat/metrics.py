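"""Threshold-anchored decompression metrics and pain outcomes.

Three competing quantifications of intraoperative threshold change are
computed per patient:

* percentage change ``(pre - post) / pre`` of the aggregated threshold,
* Threshold Reduction Ratio (TRR) — the fraction of baseline elevation
  above the physiologic reference (default 2.0 mA) eliminated by
  decompression, averaged over the nerves that had any elevation,
* Threshold Excess (TE) — the residual aggregated post-decompression
  threshold above the reference, clamped at zero (mA).

TRR is dimensionless and <= 1 (1 = complete normalization); it is undefined
for a patient whose nerves all started at or below the reference, because
there is no elevation to reduce.  TE is an absolute residual-pathology
benchmark and is always >= 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .cohort import (
    Aggregation,
    Cohort,
    MetricConfig,
    NerveMeasurement,
    PatientRecord,
)

METRICS_COLUMNS = (
    "patient_id",
    "region",
    "n_nerves",
    "mean_pre_mA",
    "mean_post_mA",
    "pct_change",
    "trr",
    "te",
    "nps_pre",
    "nps_6wk",
    "pain_improvement_frac",
    "mcid",
    "complete_relief",
    "aggregation_used",
)


def nerve_trr(pre_mA: float, post_mA: float, reference_mA: float = 2.0) -> float | None:
    """Threshold Reduction Ratio of a single nerve.

    ``((pre - R) - max(post - R, 0)) / (pre - R)``.  Undefined (``None``)
    when the nerve has no baseline elevation (``pre <= R``): there is
    nothing to reduce and the ratio would be 0/0.  Post-decompression
    elevation clamps at zero, so overshooting below the reference still
    scores 1.  A worsening nerve yields a negative ratio (not clamped).
    """
    baseline_elev = pre_mA - reference_mA
    if baseline_elev <= 0:
        return None
    post_elev = max(post_mA - reference_mA, 0.0)
    return (baseline_elev - post_elev) / baseline_elev


def patient_trr(
    nerves: Sequence[NerveMeasurement], reference_mA: float = 2.0
) -> float | None:
    """Mean nerve-level TRR over the nerves with baseline elevation.

    ``None`` when no nerve was elevated above the reference.
    """
    ratios = [
        r
        for nv in nerves
        if (r := nerve_trr(nv.pre_mA, nv.post_mA, reference_mA)) is not None
    ]
    if not ratios:
        return None
    return float(np.mean(ratios))


def select_nerve(
    nerves: Sequence[NerveMeasurement], strategy: Literal["index", "worst"]
) -> NerveMeasurement:
    """Pick the summary nerve: highest pre threshold (``index``) or highest
    post threshold (``worst``); ties go to the first in input order."""
    if not nerves:
        raise ValueError("nerve list is empty")
    if strategy == "index":
        return max(nerves, key=lambda nv: nv.pre_mA)  # max keeps first on ties
    if strategy == "worst":
        return max(nerves, key=lambda nv: nv.post_mA)
    raise ValueError(f"unknown selection strategy {strategy!r}")


def _aggregate(
    nerves: Sequence[NerveMeasurement], aggregation: Aggregation
) -> tuple[float, float]:
    """(aggregated pre, aggregated post) under the chosen strategy."""
    if not nerves:
        raise ValueError("nerve list is empty")
    if aggregation == "mean":
        return (
            float(np.mean([nv.pre_mA for nv in nerves])),
            float(np.mean([nv.post_mA for nv in nerves])),
        )
    nv = select_nerve(nerves, aggregation)
    return nv.pre_mA, nv.post_mA


def patient_te(
    nerves: Sequence[NerveMeasurement],
    reference_mA: float = 2.0,
    aggregation: Aggregation = "mean",
) -> float:
    """Threshold Excess: ``max(aggregated post - R, 0)`` in mA."""
    _, post = _aggregate(nerves, aggregation)
    return max(post - reference_mA, 0.0)


def patient_pct_change(
    nerves: Sequence[NerveMeasurement], aggregation: Aggregation = "mean"
) -> float | None:
    """Fractional threshold reduction ``(pre - post) / pre`` of the
    aggregated thresholds; ``None`` if the aggregated pre is zero."""
    pre, post = _aggregate(nerves, aggregation)
    if pre == 0:
        return None
    return (pre - post) / pre


class PainOutcome(NamedTuple):
    improvement_frac: float | None
    mcid: bool
    complete_relief: bool


def pain_outcomes(
    nps_pre: int, nps_6wk: int, config: MetricConfig = MetricConfig()
) -> PainOutcome:
    """Pain-outcome triple from the two NPS scores.

    The improvement fraction ``(pre - post) / pre`` is undefined at zero
    baseline.  MCID is the disjunction of an absolute reduction of at least
    ``mcid_points`` and a relative improvement of at least
    ``mcid_fraction``; complete relief is a six-week score of exactly 0.
    """
    if not (0 <= nps_pre <= 10 and 0 <= nps_6wk <= 10):
        raise ValueError("NPS scores must lie in [0, 10]")
    drop = nps_pre - nps_6wk
    frac = drop / nps_pre if nps_pre > 0 else None
    mcid = drop >= config.mcid_points or (
        frac is not None and frac >= config.mcid_fraction
    )
    return PainOutcome(frac, bool(mcid), nps_6wk == 0)


@dataclass(frozen=True)
class PatientMetrics:
    """All derived quantities for one patient."""

    patient_id: str
    region: str
    n_nerves: int
    mean_pre_mA: float
    mean_post_mA: float
    pct_change: float | None
    trr: float | None
    te: float
    nps_pre: int
    nps_6wk: int
    pain_improvement_frac: float | None
    mcid: bool
    complete_relief: bool
    aggregation_used: Aggregation


def compute_patient_metrics(
    patient: PatientRecord, config: MetricConfig = MetricConfig()
) -> PatientMetrics:
    """Derive a :class:`PatientMetrics` under the configured aggregation.

    ``mean_pre_mA``/``mean_post_mA`` are always plain means (descriptive);
    pct_change and TE follow the aggregation strategy.  Under ``mean``
    aggregation TRR is the mean across elevated nerves; under ``index`` or
    ``worst`` it is the selected nerve's own ratio, mirroring single-nerve
    sensitivity analyses.
    """
    R = config.reference_mA
    agg = config.aggregation
    if agg == "mean":
        trr = patient_trr(patient.nerves, R)
    else:
        nv = select_nerve(patient.nerves, agg)
        trr = nerve_trr(nv.pre_mA, nv.post_mA, R)
    frac, mcid, relief = pain_outcomes(patient.nps_pre, patient.nps_6wk, config)
    return PatientMetrics(
        patient_id=patient.patient_id,
        region=patient.region,
        n_nerves=patient.n_nerves,
        mean_pre_mA=float(np.mean([nv.pre_mA for nv in patient.nerves])),
        mean_post_mA=float(np.mean([nv.post_mA for nv in patient.nerves])),
        pct_change=patient_pct_change(patient.nerves, agg),
        trr=trr,
        te=patient_te(patient.nerves, R, agg),
        nps_pre=patient.nps_pre,
        nps_6wk=patient.nps_6wk,
        pain_improvement_frac=frac,
        mcid=mcid,
        complete_relief=relief,
        aggregation_used=agg,
    )


def compute_metrics(
    cohort: Cohort, config: MetricConfig = MetricConfig()
) -> pd.DataFrame:
    """Patient-metrics table for a whole cohort (one row per patient).

    Undefined TRR / improvement fractions are NaN in the frame and empty in
    the CSV written from it.
    """
    rows = []
    for p in cohort.patients:
        m = compute_patient_metrics(p, config)
        rows.append(
            {
                "patient_id": m.patient_id,
                "region": m.region,
                "n_nerves": m.n_nerves,
                "mean_pre_mA": m.mean_pre_mA,
                "mean_post_mA": m.mean_post_mA,
                "pct_change": np.nan if m.pct_change is None else m.pct_change,
                "trr": np.nan if m.trr is None else m.trr,
                "te": m.te,
                "nps_pre": m.nps_pre,
                "nps_6wk": m.nps_6wk,
                "pain_improvement_frac": (
                    np.nan
                    if m.pain_improvement_frac is None
                    else m.pain_improvement_frac
                ),
                "mcid": m.mcid,
                "complete_relief": m.complete_relief,
                "aggregation_used": m.aggregation_used,
            }
        )
    return pd.DataFrame(rows, columns=list(METRICS_COLUMNS))


@dataclass(frozen=True)
class NerveLevelSummary:
    """Nerve-level change summary across a cohort.

    ``n_improved`` counts elevated nerves whose threshold dropped by at
    least the configured minimum; ``n_normalized`` counts improvers that
    reached the reference or below.  ``mean_pct_reduction`` is the mean of
    per-nerve fractional reductions (mean of ratios), which differs from the
    ratio of mean reduction to mean baseline; both views are recoverable
    from the fields.
    """

    n_nerves: int
    n_elevated: int
    n_improved: int
    n_normalized: int
    n_worsened: int
    mean_pre_mA: float
    sd_pre_mA: float
    mean_post_mA: float
    sd_post_mA: float
    mean_reduction_mA: float
    sd_reduction_mA: float
    mean_pct_reduction: float

    @property
    def frac_elevated(self) -> float:
        return self.n_elevated / self.n_nerves


def nerve_level_summary(
    cohort: Cohort, config: MetricConfig = MetricConfig()
) -> NerveLevelSummary:
    """Pool every nerve in the cohort and summarize threshold changes."""
    pre = np.array([nv.pre_mA for nv in cohort.nerves()], dtype=float)
    post = np.array([nv.post_mA for nv in cohort.nerves()], dtype=float)
    if pre.size == 0:
        raise ValueError("cohort has no nerves")
    R = config.reference_mA
    elevated = pre > R
    improved = elevated & (pre - post >= config.min_improvement_mA)
    normalized = improved & (post <= R)
    reduction = pre - post
    return NerveLevelSummary(
        n_nerves=int(pre.size),
        n_elevated=int(elevated.sum()),
        n_improved=int(improved.sum()),
        n_normalized=int(normalized.sum()),
        n_worsened=int((post > pre).sum()),
        mean_pre_mA=float(pre.mean()),
        sd_pre_mA=float(pre.std(ddof=1)) if pre.size > 1 else math.nan,
        mean_post_mA=float(post.mean()),
        sd_post_mA=float(post.std(ddof=1)) if post.size > 1 else math.nan,
        mean_reduction_mA=float(reduction.mean()),
        sd_reduction_mA=float(reduction.std(ddof=1)) if pre.size > 1 else math.nan,
        mean_pct_reduction=float(np.mean(reduction / pre)),
    )
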