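"""Internal validation of metric -> outcome linear models.

Leave-one-out and k-fold cross-validation of simple linear regressions,
with the summary statistics used to judge whether an apparent correlation
generalizes: the cross-validated correlation (between held-out predictions
and actual outcomes), shrinkage (percentage drop from apparent to
cross-validated correlation), cross-validated R^2 (defined as the square of
the cross-validated correlation), RMSE of held-out prediction errors, and
the mean held-out slope.

LOOCV carries no randomness and is bit-deterministic; k-fold partitions are
seeded and stratified on the outcome's median to reduce fold-assignment
variance.  Both run through one shared code path (LOOCV is n-fold with
singleton folds), so ``k = n`` reproduces LOOCV exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .inference import InsufficientDataError


class CrossValError(ValueError):
    pass


class DegenerateFoldError(CrossValError):
    def __init__(self, message: str, fold: int):
        super().__init__(message)
        self.fold = fold


@dataclass(frozen=True)
class CrossValResult:
    metric_name: str
    n: int
    k: int
    apparent_r: float
    apparent_r2: float
    cv_r: float
    cv_r2: float
    shrinkage_pct: float
    r2_loss_pct: float
    rmse: float
    loocv_beta: float
    predictions: tuple[float, ...]
    fold_assignments: tuple[int, ...]
    seed: int | None = None

    @property
    def fold_predictions(self) -> pd.DataFrame:
        """Per-observation audit trail of held-out predictions."""
        return pd.DataFrame(
            {"fold": self.fold_assignments, "prediction": self.predictions}
        )


def _cv_linear(
    x: np.ndarray,
    y: np.ndarray,
    folds: Sequence[np.ndarray],
    metric_name: str,
    seed: int | None,
) -> CrossValResult:
    n = x.size
    # Training-set sums by downdating the full-data totals with each fold's
    # contribution; identical arithmetic for LOOCV and k-fold.
    Sx, Sy = x.sum(), y.sum()
    Sxx, Sxy = (x * x).sum(), (x * y).sum()

    pred = np.empty(n)
    assign = np.empty(n, dtype=int)
    slopes = np.empty(len(folds))
    order = sorted(range(len(folds)), key=lambda f: int(folds[f].min()))
    for rank, f in enumerate(order):
        idx = folds[f]
        nt = n - idx.size
        sx = Sx - x[idx].sum()
        sy = Sy - y[idx].sum()
        sxx = Sxx - (x[idx] * x[idx]).sum()
        sxy = Sxy - (x[idx] * y[idx]).sum()
        denom = sxx - sx * sx / nt
        if denom <= 1e-12 * max(sxx, 1.0):
            raise DegenerateFoldError(
                f"constant predictor in training data of fold {rank}", rank
            )
        slope = (sxy - sx * sy / nt) / denom
        intercept = (sy - slope * sx) / nt
        pred[idx] = intercept + slope * x[idx]
        assign[idx] = rank
        slopes[rank] = slope

    apparent_r = float(np.corrcoef(x, y)[0, 1])
    cv_r = float(np.corrcoef(y, pred)[0, 1])
    shrink = (
        100.0 * (abs(apparent_r) - cv_r) / abs(apparent_r)
        if apparent_r != 0
        else math.nan
    )
    ap_r2, cv_r2 = apparent_r**2, cv_r**2
    return CrossValResult(
        metric_name=metric_name,
        n=int(n),
        k=len(folds),
        apparent_r=apparent_r,
        apparent_r2=ap_r2,
        cv_r=cv_r,
        cv_r2=cv_r2,
        shrinkage_pct=shrink,
        r2_loss_pct=100.0 * (ap_r2 - cv_r2) / ap_r2 if ap_r2 > 0 else math.nan,
        rmse=float(np.sqrt(np.mean((y - pred) ** 2))),
        loocv_beta=float(slopes.mean()),
        predictions=tuple(pred),
        fold_assignments=tuple(int(a) for a in assign),
        seed=seed,
    )


def _check_xy(predictor_values, outcome_values) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(predictor_values, dtype=float)
    y = np.asarray(outcome_values, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise CrossValError("predictor and outcome must be 1-d and equal length")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise CrossValError("inputs must be finite")
    return x, y


def loocv_linear(
    predictor_values: Sequence[float],
    outcome_values: Sequence[float],
    metric_name: str = "metric",
) -> CrossValResult:
    """Leave-one-out cross-validation of ``outcome ~ predictor``.

    For each observation i, a simple linear regression is fit on the other
    n - 1 pairs and used to predict outcome_i; the result collects the
    held-out predictions and the summary statistics.  Deterministic.
    """
    x, y = _check_xy(predictor_values, outcome_values)
    if x.size < 5:
        raise InsufficientDataError(f"need n >= 5 for LOOCV, got {x.size}")
    folds = [np.array([i]) for i in range(x.size)]
    return _cv_linear(x, y, folds, metric_name, seed=None)


def kfold_linear(
    predictor_values: Sequence[float],
    outcome_values: Sequence[float],
    k: int,
    seed: int = 17,
    metric_name: str = "metric",
) -> CrossValResult:
    """Seeded k-fold cross-validation with outcome-median stratification.

    Observations above and below the outcome median are shuffled separately
    and dealt round-robin into k near-equal folds; the fold assignment is
    recorded in the result for reproducibility.  ``k = n`` reproduces LOOCV.
    """
    x, y = _check_xy(predictor_values, outcome_values)
    n = x.size
    if not 2 <= k <= n:
        raise CrossValError(f"need 2 <= k <= n (k={k}, n={n})")
    rng = np.random.default_rng(seed)
    med = np.median(y)
    upper = np.flatnonzero(y >= med)
    lower = np.flatnonzero(y < med)
    dealt: list[list[int]] = [[] for _ in range(k)]
    pos = 0
    for stratum in (upper, lower):
        for i in rng.permutation(stratum):
            dealt[pos % k].append(int(i))
            pos += 1
    folds = [np.array(sorted(f), dtype=int) for f in dealt if f]
    if len(folds) < k:
        raise CrossValError("empty fold produced; lower k")
    return _cv_linear(x, y, folds, metric_name, seed=seed)


def compare_metrics_cv(
    metrics_table: pd.DataFrame,
    metric_names: Sequence[str] = ("trr", "pct_change", "te"),
) -> list[CrossValResult]:
    """LOOCV of each quantification metric against the pain-improvement
    fraction, ranked by cross-validated correlation magnitude.

    TRR runs on its defined subset (patients with baseline elevation);
    percentage change and TE run on every patient with baseline pain —
    the same exclusion rules as the apparent analyses.
    """
    results = []
    for name in metric_names:
        df = metrics_table.dropna(subset=[name, "pain_improvement_frac"])
        results.append(
            loocv_linear(
                df[name].to_numpy(dtype=float),
                df["pain_improvement_frac"].to_numpy(dtype=float),
                metric_name=name,
            )
        )
    return sorted(results, key=lambda r: abs(r.cv_r), reverse=True)
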