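import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import assume, given
from hypothesis import strategies as st
from scipy import stats

from mmgstrat.inference import (
    DegenerateInputError,
    DegenerateOutcomeError,
    InsufficientDataError,
    SeparationError,
    SingularDesignError,
    UndefinedMarginError,
    Z95,
    adjusted_trr_model,
    correlation_pvalue,
    fisher_ci,
    logistic_fit,
    odds_ratio_2x2,
    ols_fit,
    pearson_with_ci,
    steiger_test,
    wilson_interval,
)

# ---------------------------------------------------------------------------
# correlations


def test_zero_correlation_gives_p_one_and_symmetric_ci():
    lo, hi = fisher_ci(0.0, 30)
    assert lo == pytest.approx(-hi)
    assert correlation_pvalue(0.0, 30) == 1.0


@given(r=st.floats(-0.99, 0.99), n=st.integers(4, 500))
def test_fisher_interval_contains_r_and_stays_in_range(r, n):
    lo, hi = fisher_ci(r, n)
    assert -1.0 <= lo <= r <= hi <= 1.0


def test_fisher_interval_width_shrinks_with_n():
    widths = [np.diff(fisher_ci(0.5, n))[0] for n in (10, 100, 10_000)]
    assert widths[0] > widths[1] > widths[2]
    assert widths[2] < 0.08


def test_pearson_with_ci_on_data():
    rng = np.random.default_rng(5)
    x = rng.normal(size=60)
    y = 0.7 * x + rng.normal(size=60)
    res = pearson_with_ci(x, y)
    assert res.ci_lo <= res.r <= res.ci_hi
    assert res.p == pytest.approx(correlation_pvalue(res.r, 60))
    assert res.p < 0.001


def test_pearson_handles_perfectly_collinear_data():
    x = np.arange(10.0)
    res = pearson_with_ci(x, 2 * x + 1)
    assert res.r == pytest.approx(1.0)
    assert res.ci_hi <= 1.0


@pytest.mark.parametrize(
    "x,y,err",
    [
        ([1, 1, 1, 1], [1, 2, 3, 4], DegenerateInputError),
        ([1, 2, 3], [1, 2, 3], InsufficientDataError),
    ],
)
def test_pearson_degenerate_inputs(x, y, err):
    with pytest.raises(err):
        pearson_with_ci(x, y)


# ---------------------------------------------------------------------------
# Steiger dependent-correlation test


def _steiger_reference(r1y, r2y, r12, n):
    """Independent transcription of the published Z formula, kept deliberately
    separate from the implementation's algebra."""
    rbar2 = ((r1y + r2y) / 2.0) ** 2
    cov = r12 * (1.0 - rbar2 - rbar2) - (rbar2 / 2.0) * (
        1.0 - rbar2 - rbar2 - r12 * r12
    )
    c = cov / ((1.0 - rbar2) * (1.0 - rbar2))
    num = 0.5 * math.log((1 + r1y) / (1 - r1y)) - 0.5 * math.log((1 + r2y) / (1 - r2y))
    return num * math.sqrt((n - 3) / (2.0 - 2.0 * c))


def test_steiger_equal_correlations_give_zero():
    z, p = steiger_test(0.5, 0.5, 0.3, 30)
    assert z == 0.0 and p == 1.0


@given(
    r1=st.floats(-0.9, 0.9), r2=st.floats(-0.9, 0.9), r12=st.floats(-0.9, 0.9),
    n=st.integers(10, 200),
)
def test_steiger_antisymmetric_and_matches_reference(r1, r2, r12, n):
    rbar2 = ((r1 + r2) / 2) ** 2
    c = (r12 * (1 - 2 * rbar2) - rbar2 / 2 * (1 - 2 * rbar2 - r12**2)) / (1 - rbar2) ** 2
    assume(abs(c) < 0.95)
    z, p = steiger_test(r1, r2, r12, n)
    z_swap, p_swap = steiger_test(r2, r1, r12, n)
    assert z == pytest.approx(-z_swap)
    assert p == pytest.approx(p_swap)
    assert z == pytest.approx(_steiger_reference(r1, r2, r12, n), abs=1e-10)


def test_steiger_dual_implementation_spot_check():
    z, _ = steiger_test(0.6, 0.3, 0.5, 50)
    assert z == pytest.approx(_steiger_reference(0.6, 0.3, 0.5, 50), abs=1e-12)
    assert z > 0


def test_steiger_numeric_degeneracy_detected():
    with pytest.raises(DegenerateInputError):
        steiger_test(0.999, 0.998, 0.5, 50)


def test_steiger_strongly_dependent_predictors_sharpen_the_comparison():
    # the same correlation gap is more significant when the two predictors
    # are themselves highly correlated
    z_weak, _ = steiger_test(0.656, 0.494, 0.3, 38)
    z_strong, p = steiger_test(0.656, 0.494, 0.85, 38)
    assert z_strong > z_weak > 0
    assert z_strong > 2.0 and p < 0.05


# ---------------------------------------------------------------------------
# OLS


def test_ols_exact_linear_data_recovered_to_machine_precision():
    x = np.linspace(0, 7, 25)
    y = 1.0 - 0.063 * x
    res = ols_fit(y, pd.DataFrame({"te": x}))
    assert res.slope() == pytest.approx(-0.063, abs=1e-12)
    assert res.coef("intercept") == pytest.approx(1.0, abs=1e-12)
    assert res.r_squared == pytest.approx(1.0)


def test_ols_rank_deficient_design_names_columns():
    x = np.arange(20.0)
    design = pd.DataFrame({"a": x, "b": 2 * x})
    with pytest.raises(SingularDesignError, match="b") as exc:
        ols_fit(x + 1, design)
    assert "b" in exc.value.columns


def test_ols_aic_drops_when_predictive_column_added(rng):
    n = 500
    x1, x2 = rng.normal(size=n), rng.normal(size=n)
    y = x1 + x2 + rng.normal(size=n)
    aic1 = ols_fit(y, pd.DataFrame({"x1": x1})).aic
    aic2 = ols_fit(y, pd.DataFrame({"x1": x1, "x2": x2})).aic
    assert aic2 < aic1


def test_ols_matches_statsmodels_ci_semantics(rng):
    # t-based CI must contain the coefficient
    x = rng.normal(size=40)
    y = 0.5 * x + rng.normal(size=40)
    res = ols_fit(y, pd.DataFrame({"x": x}))
    lo, hi = res.ci("x")
    assert lo <= res.coef("x") <= hi


def test_adjusted_model_null_covariates_cover_zero():
    """When improvement depends on TRR alone, the covariate CIs behave like
    95% intervals around zero: averaged over replicates, nearly all of
    them cover it and the TRR effect is recovered."""
    n, covered, total, trr_coefs = 300, 0, 0, []
    for seed in range(20):
        rng = np.random.default_rng(seed)
        trr = rng.uniform(0, 1, n)
        df = pd.DataFrame(
            {
                "trr": trr,
                "pain_improvement_frac": 0.2 + 0.6 * trr + rng.normal(0, 0.1, n),
                "nps_pre": rng.integers(1, 11, n),
                "n_nerves": rng.integers(1, 7, n),
                "region": rng.choice(["lumbar", "cervical"], n),
            }
        )
        res = adjusted_trr_model(df)
        trr_coefs.append(res.coef("trr"))
        for name in ("nps_pre", "n_nerves", "region_cervical"):
            lo, hi = res.ci(name)
            covered += lo <= 0.0 <= hi
            total += 1
    assert np.mean(trr_coefs) == pytest.approx(0.6, abs=0.02)
    assert covered / total >= 0.85  # nominal 95%


def test_adjusted_model_constant_trr_is_singular():
    df = pd.DataFrame(
        {
            "trr": np.ones(30),
            "pain_improvement_frac": np.linspace(0, 1, 30),
            "nps_pre": np.arange(30) % 10 + 1,
            "n_nerves": np.arange(30) % 5 + 1,
            "region": ["lumbar"] * 30,
        }
    )
    with pytest.raises(SingularDesignError):
        adjusted_trr_model(df)


# ---------------------------------------------------------------------------
# logistic regression


def _grid_mle(y, x):
    """Coarse-to-fine grid search of the Bernoulli log-likelihood."""

    def loglik(b0, b1):
        eta = b0 + b1 * x
        return np.sum(y * eta - np.log1p(np.exp(eta)))

    b0, b1, span = 0.0, 0.0, 8.0
    for _ in range(12):
        grid0 = np.linspace(b0 - span, b0 + span, 41)
        grid1 = np.linspace(b1 - span, b1 + span, 41)
        best = max(itertools.product(grid0, grid1), key=lambda g: loglik(*g))
        b0, b1 = best
        span /= 5.0
    return b0, b1


def test_logistic_mle_matches_grid_search_on_small_instance():
    x = np.arange(10.0)
    y = np.array([0, 0, 1, 0, 1, 1, 0, 1, 1, 1], dtype=float)
    res = logistic_fit(y.astype(bool), x, bootstrap_reps=0)
    b0, b1 = _grid_mle(y, x)
    assert res.intercept == pytest.approx(b0, abs=1e-4)
    assert res.slope_coef == pytest.approx(b1, abs=1e-4)
    assert res.or_per_unit == pytest.approx(math.exp(b1), rel=1e-3)


def test_logistic_constant_predictor_is_flat():
    y = np.array([True, False] * 6)
    res = logistic_fit(y, np.full(12, 3.0), bootstrap_reps=0)
    assert res.or_per_unit == 1.0 and res.slope_coef == 0.0
    assert res.wald_ci_lo <= 1.0 <= res.wald_ci_hi


def test_logistic_separation_detected():
    x = np.arange(20.0)
    y = x > 9.5
    with pytest.raises(SeparationError):
        logistic_fit(y, x, bootstrap_reps=0)


def test_logistic_single_class_rejected():
    with pytest.raises(DegenerateOutcomeError):
        logistic_fit(np.ones(12, dtype=bool), np.arange(12.0), bootstrap_reps=0)


def test_logistic_parameter_recovery_and_wald_calibration():
    """The MLE recovers a per-unit OR of 0.6 on average and the Wald CI
    covers the truth at close to its nominal rate over replicates."""
    n, cover, ors = 500, 0, []
    for seed in range(30):
        rng = np.random.default_rng(seed)
        te = rng.uniform(0, 7, n)
        p = 1 / (1 + np.exp(-(0.8 + math.log(0.6) * te)))
        y = rng.random(n) < p
        res = logistic_fit(y, te, bootstrap_reps=0)
        ors.append(res.or_per_unit)
        cover += res.wald_ci_lo <= 0.6 <= res.wald_ci_hi
    assert np.mean(ors) == pytest.approx(0.6, abs=0.02)
    assert cover / 30 >= 0.85  # nominal 95%


def test_logistic_bootstrap_interval_brackets_the_estimate(rng):
    te = rng.uniform(0, 7, 200)
    p = 1 / (1 + np.exp(-(0.8 + math.log(0.6) * te)))
    y = rng.random(200) < p
    res = logistic_fit(y, te, bootstrap_reps=200, seed=11)
    assert res.n_bootstrap_effective > 150
    assert res.bootstrap_ci_lo <= res.or_per_unit <= res.bootstrap_ci_hi
    assert res.predicted_probability(0.0) > res.predicted_probability(7.0)


# ---------------------------------------------------------------------------
# 2x2 tables


def _fisher_enumeration(a, b, c, d):
    """Brute-force two-sided Fisher p: sum hypergeometric pmf over all tables
    with the observed margins whose probability does not exceed the
    observed table's."""
    r1, n1, ncol = a + b, a + c, a + b + c + d
    support = range(max(0, r1 + n1 - ncol), min(r1, n1) + 1)
    pmf = {k: stats.hypergeom.pmf(k, ncol, r1, n1) for k in support}
    p_obs = pmf[a]
    return sum(p for p in pmf.values() if p <= p_obs * (1 + 1e-9))


def test_odds_ratio_example_and_exact_p():
    res = odds_ratio_2x2(13, 4, 8, 15)
    assert res.odds_ratio == pytest.approx(6.09375)
    assert res.exact_p == pytest.approx(_fisher_enumeration(13, 4, 8, 15), abs=1e-12)
    assert not res.continuity_corrected


def test_odds_ratio_uniform_table():
    res = odds_ratio_2x2(1, 1, 1, 1)
    assert res.odds_ratio == 1.0 and res.exact_p == pytest.approx(1.0)


def test_odds_ratio_zero_cell_continuity_corrected():
    res = odds_ratio_2x2(5, 0, 2, 3)
    assert res.continuity_corrected
    assert res.odds_ratio == pytest.approx((5.5 * 3.5) / (0.5 * 2.5))


def test_odds_ratio_empty_margin_rejected():
    with pytest.raises(UndefinedMarginError):
        odds_ratio_2x2(0, 0, 3, 4)


@given(
    a=st.integers(0, 15), b=st.integers(0, 15),
    c=st.integers(0, 15), d=st.integers(0, 15),
)
def test_exact_p_matches_enumeration(a, b, c, d):
    if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
        return
    res = odds_ratio_2x2(a, b, c, d)
    assert res.exact_p == pytest.approx(_fisher_enumeration(a, b, c, d), abs=1e-9)


# ---------------------------------------------------------------------------
# Wilson intervals


def _wilson_bisect(k, n, z=Z95):
    """Invert the score equation (phat - p)^2 = z^2 p (1 - p) / n by
    bisection, independently of the closed form."""
    phat = k / n

    def g(p):
        return (phat - p) ** 2 - z * z * p * (1 - p) / n

    def root(lo, hi):
        for _ in range(200):
            mid = (lo + hi) / 2
            if (g(lo) <= 0) == (g(mid) <= 0):
                lo = mid
            else:
                hi = mid
        return (lo + hi) / 2

    lo = 0.0 if g(0.0) <= 0 else root(0.0, phat)
    hi = 1.0 if g(1.0) <= 0 else root(phat, 1.0)
    return lo, hi


@pytest.mark.parametrize(
    "k,n,lo,hi",
    [(13, 17, 0.527, 0.904), (2, 8, 0.071, 0.591), (0, 10, 0.0, None), (10, 10, None, 1.0)],
)
def test_wilson_examples(k, n, lo, hi):
    ci = wilson_interval(k, n)
    if lo is not None:
        assert ci.lo == pytest.approx(lo, abs=5e-4)
    if hi is not None:
        assert ci.hi == pytest.approx(hi, abs=5e-4)
    assert 0.0 <= ci.lo <= ci.point <= ci.hi <= 1.0


@given(n=st.integers(1, 500), frac=st.floats(0, 1))
def test_wilson_matches_bisection_inversion(n, frac):
    k = round(frac * n)
    ci = wilson_interval(k, n)
    lo, hi = _wilson_bisect(k, n)
    assert ci.lo == pytest.approx(lo, abs=1e-9)
    assert ci.hi == pytest.approx(hi, abs=1e-9)
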