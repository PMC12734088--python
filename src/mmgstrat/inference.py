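"""Inferential statistics for metric-outcome analyses.

Implements the estimator set the pipeline reports: Pearson correlations
with Fisher-z confidence intervals and t-based p-values, the Steiger (1980)
Z-test for two dependent correlations sharing a variable, ordinary least
squares dose-response fits (simple and covariate-adjusted), logistic
regression with Wald and patient-resampling bootstrap intervals, 2x2 odds
ratios with the Fisher exact test, and Wilson score intervals for binomial
proportions.

The confidence level is fixed at 95% with z = 1.959964 throughout; rounding
to display precision is the report layer's job.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

Z95 = 1.959964


class InferenceError(ValueError):
    """Base class for statistical-input failures."""


class InsufficientDataError(InferenceError):
    pass


class DegenerateInputError(InferenceError):
    pass


class SingularDesignError(InferenceError):
    def __init__(self, message: str, columns: Sequence[str] = ()):
        super().__init__(message)
        self.columns = list(columns)


class SeparationError(InferenceError):
    pass


class DegenerateOutcomeError(InferenceError):
    pass


class UndefinedMarginError(InferenceError):
    pass


# ---------------------------------------------------------------------------
# correlations

@dataclass(frozen=True)
class CorrelationResult:
    r: float
    n: int
    ci_lo: float
    ci_hi: float
    p: float


def fisher_ci(r: float, n: int, z: float = Z95) -> tuple[float, float]:
    """95% CI for a Pearson correlation via the Fisher z transform:
    ``tanh(atanh(r) +/- z / sqrt(n - 3))``."""
    if n < 4:
        raise InsufficientDataError(f"need n >= 4 for a Fisher-z interval, got {n}")
    # |r| = 1 arises from exactly collinear data; keep atanh finite
    r = min(max(r, -1.0 + 1e-15), 1.0 - 1e-15)
    zr = math.atanh(r)
    hw = z / math.sqrt(n - 3)
    return math.tanh(zr - hw), math.tanh(zr + hw)


def correlation_pvalue(r: float, n: int) -> float:
    """Two-sided p for H0: rho = 0 from ``t = r sqrt(n-2) / sqrt(1-r^2)``
    against Student-t with n-2 degrees of freedom."""
    if n < 4:
        raise InsufficientDataError(f"need n >= 4, got {n}")
    if abs(r) >= 1.0:
        return 0.0
    t = r * math.sqrt(n - 2) / math.sqrt(1.0 - r * r)
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def pearson_with_ci(x_values: Sequence[float], y_values: Sequence[float]) -> CorrelationResult:
    """Pearson r with Fisher-z 95% CI and t-based two-sided p-value."""
    x = np.asarray(x_values, dtype=float)
    y = np.asarray(y_values, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InferenceError("x and y must be 1-d and the same length")
    if x.size < 4:
        raise InsufficientDataError(f"need n >= 4 pairs, got {x.size}")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise DegenerateInputError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("zero variance in x or y")
    r = float(np.corrcoef(x, y)[0, 1])
    lo, hi = fisher_ci(r, x.size)
    return CorrelationResult(r=r, n=int(x.size), ci_lo=lo, ci_hi=hi,
                             p=correlation_pvalue(r, x.size))


class SteigerResult(NamedTuple):
    z: float
    p: float


def steiger_test(r1y: float, r2y: float, r12: float, n: int) -> SteigerResult:
    """Steiger (1980) Z for two dependent correlations sharing variable y.

    Compares r(x1, y) with r(x2, y) given the inter-predictor correlation
    r(x1, x2), using the averaged-correlation covariance term: with
    rbar = (r1y + r2y)/2 and

        c = [r12 (1 - 2 rbar^2) - rbar^2 (1 - 2 rbar^2 - r12^2) / 2]
            / (1 - rbar^2)^2,

    Z = (atanh(r1y) - atanh(r2y)) sqrt(n - 3) / sqrt(2 - 2c); p is
    two-sided standard normal.
    """
    if n < 4:
        raise InsufficientDataError(f"need n >= 4, got {n}")
    for name, r in (("r1y", r1y), ("r2y", r2y), ("r12", r12)):
        if not -1.0 < r < 1.0:
            raise DegenerateInputError(f"{name} must lie strictly in (-1, 1), got {r}")
    rbar = (r1y + r2y) / 2.0
    c = (r12 * (1 - 2 * rbar**2) - 0.5 * rbar**2 * (1 - 2 * rbar**2 - r12**2)) / (
        (1 - rbar**2) ** 2
    )
    if abs(c) >= 1.0:
        raise DegenerateInputError(f"covariance term |c| >= 1 (c = {c:.6g})")
    z = (math.atanh(r1y) - math.atanh(r2y)) * math.sqrt(n - 3) / math.sqrt(2 - 2 * c)
    return SteigerResult(z=float(z), p=float(2.0 * stats.norm.sf(abs(z))))


# ---------------------------------------------------------------------------
# regression

@dataclass(frozen=True)
class RegressionResult:
    """OLS fit summary; coefficient order is ('intercept', *design columns)."""

    names: tuple[str, ...]
    coefficients: tuple[float, ...]
    se: tuple[float, ...]
    ci_lo: tuple[float, ...]
    ci_hi: tuple[float, ...]
    p: tuple[float, ...]
    r_squared: float
    n: int
    aic: float

    def coef(self, name: str) -> float:
        return self.coefficients[self.names.index(name)]

    def slope(self) -> float:
        """Convenience for single-predictor fits."""
        if len(self.names) != 2:
            raise ValueError("slope() requires exactly one predictor")
        return self.coefficients[1]

    def ci(self, name: str) -> tuple[float, float]:
        i = self.names.index(name)
        return self.ci_lo[i], self.ci_hi[i]


def _find_collinear(X: np.ndarray, names: Sequence[str]) -> list[str]:
    bad = []
    for j in range(1, X.shape[1]):
        prev = X[:, :j]
        resid = X[:, j] - prev @ np.linalg.lstsq(prev, X[:, j], rcond=None)[0]
        scale = np.linalg.norm(X[:, j]) or 1.0
        if np.linalg.norm(resid) / scale < 1e-10:
            bad.append(names[j])
    return bad


def ols_fit(y_values: Sequence[float], design: pd.DataFrame) -> RegressionResult:
    """OLS with intercept: t-based 95% CIs (n - p df), R^2, Gaussian AIC.

    ``design`` holds the predictor columns only; the intercept is added
    here.  A rank-deficient design raises :class:`SingularDesignError`
    naming the collinear column(s).
    """
    y = np.asarray(y_values, dtype=float)
    X = np.column_stack([np.ones(len(y)), design.to_numpy(dtype=float)])
    names = ("intercept", *map(str, design.columns))
    if y.size <= X.shape[1] + 1:
        raise InsufficientDataError(
            f"need n > p + 1 observations (n={y.size}, p={X.shape[1]})"
        )
    if np.linalg.matrix_rank(X) < X.shape[1]:
        cols = _find_collinear(X, names)
        raise SingularDesignError(f"design is rank-deficient: {cols}", cols)
    fit = sm.OLS(y, X).fit()
    ci = fit.conf_int(alpha=0.05)
    return RegressionResult(
        names=names,
        coefficients=tuple(float(v) for v in fit.params),
        se=tuple(float(v) for v in fit.bse),
        ci_lo=tuple(float(v) for v in ci[:, 0]),
        ci_hi=tuple(float(v) for v in ci[:, 1]),
        p=tuple(float(v) for v in fit.pvalues),
        r_squared=float(fit.rsquared),
        n=int(y.size),
        aic=float(fit.aic),
    )


def adjusted_trr_model(cohort_metrics: pd.DataFrame) -> RegressionResult:
    """Covariate-adjusted TRR model: OLS of the pain-improvement fraction on
    TRR, baseline NPS, nerve count, and a cervical-region indicator, over
    the patients with defined TRR and baseline pain."""
    df = cohort_metrics.dropna(subset=["trr", "pain_improvement_frac"])
    design = pd.DataFrame(
        {
            "trr": df["trr"].to_numpy(dtype=float),
            "nps_pre": df["nps_pre"].to_numpy(dtype=float),
            "n_nerves": df["n_nerves"].to_numpy(dtype=float),
            "region_cervical": (df["region"] == "cervical").to_numpy(dtype=float),
        }
    )
    return ols_fit(df["pain_improvement_frac"].to_numpy(dtype=float), design)


# ---------------------------------------------------------------------------
# logistic regression

@dataclass(frozen=True)
class LogisticResult:
    or_per_unit: float
    wald_ci_lo: float
    wald_ci_hi: float
    bootstrap_ci_lo: float
    bootstrap_ci_hi: float
    p: float
    aic: float
    intercept: float
    slope_coef: float
    n: int
    bootstrap_reps: int
    bootstrap_seed: int
    n_bootstrap_effective: int

    def predicted_probability(self, predictor_value: float) -> float:
        """Model probability of the outcome at a predictor value."""
        eta = self.intercept + self.slope_coef * predictor_value
        return float(1.0 / (1.0 + math.exp(-eta)))


def _fit_logit(y: np.ndarray, x: np.ndarray):
    X = np.column_stack([np.ones_like(x), x])
    with warnings.catch_warnings():
        warnings.simplefilter("error")
        model = sm.Logit(y, X)
        res = model.fit(method="newton", maxiter=100, tol=1e-8, disp=0)
    if not res.mle_retvals.get("converged", True) or np.abs(res.params).max() > 1e3:
        raise SeparationError("logistic fit did not converge (separation?)")
    return res


def logistic_fit(
    binary_outcome: Sequence[bool],
    predictor: Sequence[float],
    bootstrap_reps: int = 2000,
    seed: int = 17,
) -> LogisticResult:
    """Single-predictor logistic regression by maximum likelihood.

    Reports the odds ratio per unit of the predictor with a Wald interval
    ``exp(b1 +/- z * SE)``, a percentile bootstrap interval over
    patient-level resamples, the Wald two-sided p, and AIC.  Resamples that
    collapse to one outcome class or separate are dropped from the
    bootstrap (the effective count is recorded).
    """
    y = np.asarray(binary_outcome, dtype=float)
    x = np.asarray(predictor, dtype=float)
    if y.size != x.size or y.ndim != 1:
        raise InferenceError("outcome and predictor must be 1-d and equal length")
    if y.size < 10:
        raise InsufficientDataError(f"need n >= 10, got {y.size}")
    if len(np.unique(y)) < 2:
        raise DegenerateOutcomeError("outcome has a single class")

    if np.ptp(x) == 0:
        # flat predictor: slope is exactly 0, the odds ratio 1, and no Wald
        # scale exists -- report the degenerate unbounded interval.
        p1 = y.mean()
        ll = y.size * (p1 * math.log(p1) + (1 - p1) * math.log(1 - p1))
        return LogisticResult(
            or_per_unit=1.0, wald_ci_lo=0.0, wald_ci_hi=math.inf,
            bootstrap_ci_lo=0.0, bootstrap_ci_hi=math.inf,
            p=1.0, aic=2 * 2 - 2 * ll,
            intercept=float(math.log(p1 / (1 - p1))), slope_coef=0.0,
            n=int(y.size), bootstrap_reps=bootstrap_reps, bootstrap_seed=seed,
            n_bootstrap_effective=0,
        )

    try:
        res = _fit_logit(y, x)
    except (SeparationError, np.linalg.LinAlgError):
        raise
    except Exception as exc:  # statsmodels separation warnings/errors
        raise SeparationError(f"logistic fit failed: {exc}") from exc

    b0, b1 = (float(v) for v in res.params)
    se1 = float(res.bse[1])

    rng = np.random.default_rng(seed)
    ors = []
    for _ in range(bootstrap_reps):
        idx = rng.integers(0, y.size, y.size)
        yb, xb = y[idx], x[idx]
        if len(np.unique(yb)) < 2 or np.ptp(xb) == 0:
            continue
        try:
            rb = _fit_logit(yb, xb)
        except Exception:
            continue
        ors.append(math.exp(float(rb.params[1])))
    if ors:
        blo, bhi = np.percentile(ors, [2.5, 97.5])
    else:
        blo = bhi = math.nan

    return LogisticResult(
        or_per_unit=math.exp(b1),
        wald_ci_lo=math.exp(b1 - Z95 * se1),
        wald_ci_hi=math.exp(b1 + Z95 * se1),
        bootstrap_ci_lo=float(blo),
        bootstrap_ci_hi=float(bhi),
        p=float(res.pvalues[1]),
        aic=float(res.aic),
        intercept=b0,
        slope_coef=b1,
        n=int(y.size),
        bootstrap_reps=bootstrap_reps,
        bootstrap_seed=seed,
        n_bootstrap_effective=len(ors),
    )


# ---------------------------------------------------------------------------
# 2x2 tables and proportions

@dataclass(frozen=True)
class ContingencyResult:
    a: int
    b: int
    c: int
    d: int
    odds_ratio: float
    exact_p: float
    continuity_corrected: bool = field(default=False)


def odds_ratio_2x2(a: int, b: int, c: int, d: int) -> ContingencyResult:
    """Odds ratio ``(a d)/(b c)`` with the two-sided Fisher exact p-value
    (summing hypergeometric probabilities no larger than the observed
    table's).  Any zero cell switches to the Haldane-Anscombe correction
    (0.5 added to every cell), flagged in the result."""
    for name, v in (("a", a), ("b", b), ("c", c), ("d", d)):
        if not (isinstance(v, (int, np.integer)) and v >= 0):
            raise InferenceError(f"count {name} must be a non-negative integer")
    if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
        raise UndefinedMarginError("a row or column margin is zero")
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    corrected = 0 in (a, b, c, d)
    if corrected:
        orr = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        orr = (a * d) / (b * c)
    return ContingencyResult(a, b, c, d, float(orr), float(p), corrected)


@dataclass(frozen=True)
class ProportionCI:
    k: int
    n: int
    point: float
    lo: float
    hi: float


def wilson_interval(k: int, n: int, z: float = Z95) -> ProportionCI:
    """Wilson score 95% interval for a binomial proportion:
    ``(p + z^2/2n +/- z sqrt(p(1-p)/n + z^2/4n^2)) / (1 + z^2/n)``.
    Well-behaved at the 0 and n boundaries (never leaves [0, 1])."""
    if n < 1 or not 0 <= k <= n:
        raise InferenceError(f"need 0 <= k <= n with n >= 1, got k={k}, n={n}")
    p = k / n
    z2 = z * z
    denom = 1.0 + z2 / n
    center = (p + z2 / (2 * n)) / denom
    hw = z * math.sqrt(p * (1 - p) / n + z2 / (4 * n * n)) / denom
    # boundary cases are exact: the score interval pins to 0 / 1 there
    lo = 0.0 if k == 0 else max(center - hw, 0.0)
    hi = 1.0 if k == n else min(center + hw, 1.0)
    return ProportionCI(k=int(k), n=int(n), point=p, lo=lo, hi=hi)
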