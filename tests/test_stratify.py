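import math

import numpy as np
import pandas as pd
import pytest

from mmgstrat.inference import (
    DegenerateOutcomeError,
    InsufficientDataError,
    wilson_interval,
)
from mmgstrat.stratify import (
    SpecCoverageError,
    StratificationError,
    Stratum,
    StratumSpec,
    TE_DEFAULT,
    TRR_DEFAULT,
    cutpoint_scan,
    plateau_check,
    stratify,
)


def _frame(te, improvement, relief, post=None, mcid=None, trr=None):
    n = len(te)
    return pd.DataFrame(
        {
            "patient_id": [f"P{i}" for i in range(n)],
            "te": te,
            "trr": trr if trr is not None else np.linspace(0, 1, n),
            "mean_post_mA": post if post is not None else np.asarray(te) + 2.0,
            "pain_improvement_frac": improvement,
            "complete_relief": relief,
            "mcid": mcid if mcid is not None else [True] * n,
        }
    )


@pytest.mark.parametrize(
    "value,expected",
    [(1.0, 0), (0.99, 1), (0.6, 1), (0.59, 2), (-0.4, 2)],
)
def test_trr_default_spec_assignment(value, expected):
    assert TRR_DEFAULT.assign(value) == expected


@pytest.mark.parametrize("value,expected", [(0.0, 0), (0.49, 0), (0.5, 1), (2.5, 2)])
def test_te_default_spec_assignment(value, expected):
    assert TE_DEFAULT.assign(value) == expected


def test_overlapping_spec_rejected():
    with pytest.raises(StratificationError):
        StratumSpec(
            "te",
            (Stratum("a", 0.0, 1.0, True, True), Stratum("b", 1.0, 2.0, True, False)),
        )


def test_stratify_counts_sum_and_wilson_matches():
    te = [0.0, 0.0, 0.2, 1.0, 1.5, 2.0, 3.0, 4.0]
    imp = [1.0, 0.9, 0.95, 0.8, 0.7, 0.75, 0.5, 0.3]
    relief = [True, True, False, True, False, False, False, False]
    out = stratify(_frame(te, imp, relief), TE_DEFAULT)
    assert [s.n for s in out] == [3, 3, 2]
    assert sum(s.n for s in out) == 8
    first = out[0]
    expected = wilson_interval(2, 3)
    assert first.relief_rate.point == pytest.approx(2 / 3)
    assert first.relief_rate.lo == pytest.approx(expected.lo)
    assert first.mean_improvement == pytest.approx(np.mean(imp[:3]))
    lo, hi = first.improvement_ci
    assert lo <= first.mean_improvement <= hi


def test_stratify_single_category_holds_everyone():
    spec = StratumSpec("te", (Stratum("all", -math.inf, math.inf, False, False),))
    out = stratify(_frame([0.1, 0.2, 0.3], [0.5, 0.6, 0.7], [True, False, True]), spec)
    assert out[0].n == 3


def test_moving_a_boundary_reassigns_without_losing_patients():
    df = _frame([0.0, 0.4, 0.6, 1.0, 2.6], [0.9, 0.8, 0.7, 0.6, 0.5], [True] * 5)
    moved = StratumSpec(
        "te",
        (
            Stratum("low", 0.0, 0.7, True, False),
            Stratum("mid", 0.7, 2.5, True, False),
            Stratum("high", 2.5, math.inf, True, False),
        ),
    )
    assert sum(s.n for s in stratify(df, TE_DEFAULT)) == 5
    assert sum(s.n for s in stratify(df, moved)) == 5


def test_undefined_stratifying_value_is_a_coverage_error():
    df = _frame([0.0, 1.0, 3.0, 0.5, 0.7], [0.9, 0.8, 0.7, 0.6, 0.5], [True] * 5,
                trr=[0.5, np.nan, 0.7, 0.8, 0.9])
    with pytest.raises(SpecCoverageError, match="P1"):
        stratify(df, TRR_DEFAULT)


def test_plateau_check_runs_on_the_te_zero_subset(rng):
    n = 30
    post = rng.uniform(1, 2, n)
    df = _frame([0.0] * n, rng.uniform(0.5, 1.0, n), [True] * n, post=post)
    res = plateau_check(df)
    assert res.n == n
    assert 0.0 <= res.p <= 1.0


def test_plateau_check_small_subset_rejected():
    df = _frame([0.0, 0.0, 0.0, 1.0, 2.0], [0.9] * 5, [True] * 5)
    with pytest.raises(InsufficientDataError):
        plateau_check(df)


def test_plateau_null_rarely_significant_over_seeds():
    hits = 0
    for seed in range(40):
        r = np.random.default_rng(seed)
        post = r.uniform(1, 2, 20)
        df = _frame([0.0] * 20, r.uniform(0.4, 1.0, 20), [True] * 20, post=post)
        hits += plateau_check(df).p < 0.05
    assert hits <= 6  # ~5% nominal; generous bound for 40 draws


def test_cutpoint_scan_hand_counted_confusion_matrix():
    post = [1.0, 2.0, 3.0, 3.0, 4.0, 5.0]
    relief = [True, True, True, False, False, False]
    df = _frame([max(p - 2, 0) for p in post], [0.9] * 6, relief, post=post)
    scan = cutpoint_scan(df, "complete_relief", candidate_cutoffs=[2.5])
    r = scan.results[0]
    assert r.sensitivity == pytest.approx(2 / 3)
    assert r.specificity == pytest.approx(1.0)
    assert r.ppv == pytest.approx(1.0)
    assert (r.tp, r.fp, r.fn, r.tn) == (2, 0, 1, 3)


def test_cutpoint_scan_perfect_predictor():
    post = [1.0, 1.5, 2.0, 4.0, 5.0, 6.0]
    relief = [True, True, True, False, False, False]
    df = _frame([max(p - 2, 0) for p in post], [0.9] * 6, relief, post=post)
    scan = cutpoint_scan(df, "complete_relief")
    assert scan.auc == pytest.approx(1.0)
    assert any(
        r.sensitivity == 1.0 and r.specificity == 1.0 for r in scan.results
    )


def test_cutpoint_scan_extreme_cutoffs(rng):
    post = rng.uniform(1, 8, 20)
    relief = rng.random(20) < 0.5
    if relief.all() or not relief.any():
        relief[0] = ~relief[0]
    df = _frame(np.maximum(post - 2, 0), [0.5] * 20, relief, post=post)
    scan = cutpoint_scan(df, "complete_relief",
                         candidate_cutoffs=[post.min() - 1, post.max() + 1])
    below, above = scan.results
    assert (below.sensitivity, below.specificity) == (0.0, 1.0)
    assert (above.sensitivity, above.specificity) == (1.0, 0.0)


def test_rank_auc_equals_trapezoid_over_exhaustive_cutoffs(rng):
    post = rng.permutation(np.linspace(1, 9, 25))  # tie-free
    p_relief = 1 / (1 + np.exp(post - 4))
    relief = rng.random(25) < p_relief
    if relief.all() or not relief.any():
        relief[0] = ~relief[0]
    df = _frame(np.maximum(post - 2, 0), [0.5] * 25, relief, post=post)
    scan = cutpoint_scan(df, "complete_relief")
    sens = np.array([0.0] + [r.sensitivity for r in scan.results] + [1.0])
    fpr = np.array([0.0] + [1 - r.specificity for r in scan.results] + [1.0])
    order = np.argsort(fpr, kind="stable")
    trapezoid = np.trapezoid(sens[order], fpr[order])
    assert scan.auc == pytest.approx(trapezoid, abs=1e-9)


def test_cutpoint_scan_single_class_outcome_rejected():
    df = _frame([0.0, 1.0, 2.0, 0.5, 0.2], [0.9] * 5, [True] * 5)
    with pytest.raises(DegenerateOutcomeError):
        cutpoint_scan(df, "complete_relief")


def test_cutpoint_scan_any_improvement_outcome():
    df = _frame([0.0, 1.0, 2.0, 3.0], [0.9, 0.5, 0.0, 0.0], [False] * 4)
    scan = cutpoint_scan(df, "any_improvement", candidate_cutoffs=[3.5])
    assert scan.results[0].outcome_name == "any_improvement"
    assert scan.results[0].tp == 2
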