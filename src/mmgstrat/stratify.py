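"""Stratified outcome tables, the sufficiency-plateau check, and
ROC-style cut-point screening.

Strata mirror the clinical presentation: ordered, disjoint, exhaustive
categories of a quantification metric (e.g. complete normalization
TRR = 1.0, substantial reduction 0.6 <= TRR < 1.0, partial reduction
TRR < 0.6), each summarized by the mean pain-improvement fraction with a
Student-t interval and the complete-relief rate with a Wilson interval.

The cut-point scan classifies a patient test-positive when the aggregated
post-decompression threshold is at or below a candidate cutoff
(equivalently TE <= cutoff - reference) and reports the confusion-matrix
rates against a chosen binary outcome, plus the rank-statistic AUC.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .inference import (
    CorrelationResult,
    DegenerateOutcomeError,
    InsufficientDataError,
    ProportionCI,
    pearson_with_ci,
    wilson_interval,
)

OUTCOME_NAMES = ("complete_relief", "mcid", "any_improvement")


class StratificationError(ValueError):
    pass


class SpecCoverageError(StratificationError):
    pass


@dataclass(frozen=True)
class Stratum:
    """Half-open or closed interval of a metric with a display label."""

    label: str
    lo: float
    hi: float
    lo_closed: bool = True
    hi_closed: bool = False

    def contains(self, v: float) -> bool:
        above = v > self.lo or (self.lo_closed and v == self.lo)
        below = v < self.hi or (self.hi_closed and v == self.hi)
        return above and below


@dataclass(frozen=True)
class StratumSpec:
    metric_name: str
    strata: tuple[Stratum, ...]

    def __post_init__(self) -> None:
        for i, s in enumerate(self.strata):
            if s.lo > s.hi:
                raise StratificationError(f"stratum {s.label!r} has lo > hi")
            for t in self.strata[i + 1 :]:
                overlap_lo = max(s.lo, t.lo)
                overlap_hi = min(s.hi, t.hi)
                if overlap_lo < overlap_hi or (
                    overlap_lo == overlap_hi
                    and all(
                        u.contains(overlap_lo) for u in (s, t) if math.isfinite(overlap_lo)
                    )
                    and math.isfinite(overlap_lo)
                ):
                    raise StratificationError(
                        f"strata {s.label!r} and {t.label!r} overlap"
                    )

    def assign(self, v: float) -> int:
        for i, s in enumerate(self.strata):
            if s.contains(v):
                return i
        raise SpecCoverageError(
            f"value {v!r} of {self.metric_name!r} falls in no stratum"
        )


#: Complete normalization / substantial reduction / partial reduction.
TRR_DEFAULT = StratumSpec(
    "trr",
    (
        Stratum("TRR = 1.0", 1.0, math.inf, True, False),
        Stratum("0.6 <= TRR < 1.0", 0.6, 1.0, True, False),
        Stratum("TRR < 0.6", -math.inf, 0.6, False, False),
    ),
)

#: At/near reference / moderate excess / substantial excess (mA).
TE_DEFAULT = StratumSpec(
    "te",
    (
        Stratum("0.0 <= TE < 0.5 mA", 0.0, 0.5, True, False),
        Stratum("0.5 <= TE < 2.5 mA", 0.5, 2.5, True, False),
        Stratum("TE >= 2.5 mA", 2.5, math.inf, True, False),
    ),
)


@dataclass(frozen=True)
class StratumSummary:
    label: str
    n: int
    mean_improvement: float
    improvement_ci: tuple[float, float]
    relief_rate: ProportionCI


def _t_interval(values: np.ndarray) -> tuple[float, float]:
    if values.size < 2:
        return (math.nan, math.nan)
    m = values.mean()
    sem = values.std(ddof=1) / math.sqrt(values.size)
    hw = stats.t.ppf(0.975, df=values.size - 1) * sem
    return (float(m - hw), float(m + hw))


def stratify(metrics_table: pd.DataFrame, stratum_spec: StratumSpec) -> list[StratumSummary]:
    """Summarize pain outcomes per stratum of the given metric.

    Operates on the patients with a defined improvement fraction; a missing
    stratifying value (e.g. undefined TRR) raises
    :class:`SpecCoverageError`, since every analyzed patient must land in
    exactly one category.
    """
    df = metrics_table.dropna(subset=["pain_improvement_frac"])
    values = df[stratum_spec.metric_name].to_numpy(dtype=float)
    if np.isnan(values).any():
        bad = df.loc[np.isnan(values), "patient_id"].tolist()
        raise SpecCoverageError(
            f"{stratum_spec.metric_name!r} undefined for patient(s) {bad}; "
            "restrict the table to the metric's defined subset first"
        )
    idx = np.array([stratum_spec.assign(v) for v in values])
    out = []
    for i, s in enumerate(stratum_spec.strata):
        sel = idx == i
        imp = df.loc[sel, "pain_improvement_frac"].to_numpy(dtype=float)
        relief = int(df.loc[sel, "complete_relief"].sum())
        out.append(
            StratumSummary(
                label=s.label,
                n=int(sel.sum()),
                mean_improvement=float(imp.mean()) if imp.size else math.nan,
                improvement_ci=_t_interval(imp),
                relief_rate=wilson_interval(relief, int(sel.sum()))
                if sel.any()
                else ProportionCI(0, 0, math.nan, math.nan, math.nan),
            )
        )
    return out


def plateau_check(metrics_table: pd.DataFrame, reference_mA: float = 2.0) -> CorrelationResult:
    """Association of further threshold reduction below the reference with
    pain improvement, among patients who reached it (TE = 0).

    A flat correlation here supports the reading of the reference as a
    functional sufficiency plateau.
    """
    df = metrics_table.dropna(subset=["pain_improvement_frac"])
    sub = df[df["te"] <= 0.0]
    if len(sub) < 4:
        raise InsufficientDataError(
            f"only {len(sub)} patients at or below the reference; need >= 4"
        )
    return pearson_with_ci(
        sub["mean_post_mA"].to_numpy(dtype=float),
        sub["pain_improvement_frac"].to_numpy(dtype=float),
    )


@dataclass(frozen=True)
class CutpointResult:
    cutoff_mA: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    n_positive_test: int
    outcome_name: str
    tp: int
    fp: int
    fn: int
    tn: int


@dataclass(frozen=True)
class CutpointScan:
    outcome_name: str
    results: tuple[CutpointResult, ...]
    auc: float
    n: int


def _outcome_vector(df: pd.DataFrame, outcome_name: str) -> np.ndarray:
    if outcome_name == "any_improvement":
        return (df["pain_improvement_frac"].to_numpy(dtype=float) > 0).astype(bool)
    if outcome_name in ("complete_relief", "mcid"):
        return df[outcome_name].to_numpy(dtype=bool)
    raise StratificationError(
        f"unknown outcome {outcome_name!r}; expected one of {OUTCOME_NAMES}"
    )


def cutpoint_scan(
    metrics_table: pd.DataFrame,
    outcome_name: str,
    candidate_cutoffs: Sequence[float] | None = None,
    reference_mA: float = 2.0,
) -> CutpointScan:
    """Screen post-decompression threshold cutoffs against a binary outcome.

    Test-positive means aggregated post threshold <= cutoff.  By default the
    candidates are the midpoints between sorted unique observed thresholds
    plus the reference itself, which exhausts the distinct confusion
    matrices.  AUC comes from the Mann-Whitney rank statistic on
    ``-mean_post_mA`` (lower thresholds score higher), with tie correction.
    """
    df = metrics_table.dropna(subset=["pain_improvement_frac"])
    post = df["mean_post_mA"].to_numpy(dtype=float)
    y = _outcome_vector(df, outcome_name)
    if y.all() or not y.any():
        raise DegenerateOutcomeError(f"outcome {outcome_name!r} has a single class")

    if candidate_cutoffs is None:
        u = np.unique(post)
        mids = (u[:-1] + u[1:]) / 2 if u.size > 1 else np.array([])
        candidate_cutoffs = sorted(set(np.concatenate([mids, [reference_mA]])))

    npos, nneg = int(y.sum()), int((~y).sum())
    results = []
    for c in candidate_cutoffs:
        test_pos = post <= c
        tp = int((test_pos & y).sum())
        fp = int((test_pos & ~y).sum())
        fn = int((~test_pos & y).sum())
        tn = int((~test_pos & ~y).sum())
        results.append(
            CutpointResult(
                cutoff_mA=float(c),
                sensitivity=tp / npos,
                specificity=tn / nneg,
                ppv=tp / (tp + fp) if tp + fp else math.nan,
                npv=tn / (tn + fn) if tn + fn else math.nan,
                n_positive_test=tp + fp,
                outcome_name=outcome_name,
                tp=tp, fp=fp, fn=fn, tn=tn,
            )
        )

    ranks = stats.rankdata(-post)  # lower threshold = higher score
    auc = (ranks[y].sum() - npos * (npos + 1) / 2) / (npos * nneg)
    return CutpointScan(
        outcome_name=outcome_name,
        results=tuple(results),
        auc=float(auc),
        n=int(y.size),
    )
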