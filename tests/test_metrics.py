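"""Evaluation statistics against independent oracles."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import davies_bouldin_score, roc_auc_score

from vfdetect import metrics as M


# ---------------------------------------------------------------------------
# Confusion metrics / BAC
# ---------------------------------------------------------------------------


def test_perfect_classifier():
    y = np.array([0, 1, 0, 1, 1])
    rep = M.confusion_metrics(y, y)
    assert rep.se == rep.sp == rep.bac == rep.acc == 100.0


def test_bac_from_printed_se_sp():
    """BAC is the unweighted mean of Se and Sp: 99.7/98.9 -> 99.3."""
    assert (99.7 + 98.9) / 2 == pytest.approx(99.3, abs=0.05)
    assert (99.2 + 96.7) / 2 == pytest.approx(98.0, abs=0.05)


def test_confusion_counts_arithmetic():
    y = np.array([1] * 10 + [0] * 20)
    pred = np.array([1] * 9 + [0] * 1 + [0] * 18 + [1] * 2)
    rep = M.confusion_metrics(y, pred)
    assert (rep.tp, rep.fn, rep.tn, rep.fp) == (9, 1, 18, 2)
    assert rep.se == pytest.approx(90.0)
    assert rep.sp == pytest.approx(90.0)
    assert rep.ppv == pytest.approx(81.82, abs=0.01)
    assert rep.acc == pytest.approx(90.0)
    assert rep.bac == pytest.approx((rep.se + rep.sp) / 2)


def test_undefined_ppv_is_nan_with_warning():
    y = np.array([1, 0, 0])
    with pytest.warns(UserWarning):
        rep = M.confusion_metrics(y, np.zeros(3, dtype=int))
    assert math.isnan(rep.ppv)


def test_bac_invariant_acc_not_under_resampling():
    """Subsampling that preserves per-class error rates keeps BAC fixed
    while total accuracy moves with the class mix."""
    y = np.array([1] * 100 + [0] * 100)
    pred = y.copy()
    pred[:20] = 0  # Se 80
    pred[100:110] = 1  # Sp 90
    full = M.confusion_metrics(y, pred)
    # keep half the negatives, preserving their 10% error rate (5 of 50 wrong)
    idx = np.r_[0:100, 100:105, 110:155]
    sub = M.confusion_metrics(y[idx], pred[idx])
    assert sub.bac == pytest.approx(full.bac)
    assert abs(sub.acc - full.acc) > 1.0


# ---------------------------------------------------------------------------
# McNemar
# ---------------------------------------------------------------------------


def _binom_tail(b, n):
    return sum(math.comb(n, k) for k in range(b, n + 1)) / 2.0**n


def test_mcnemar_balanced_discordance():
    y = np.zeros(40, dtype=int)
    y[::2] = 1
    pa = y.copy()
    pb = y.copy()
    pa[:10] = 1 - pa[:10]   # A wrong on 10
    pb[30:] = 1 - pb[30:]   # B wrong on 10 (disjoint)
    p, b, c = M.mcnemar_test(y, pa, pb)
    assert (b, c) == (10, 10)
    assert p > 0.05
    assert p == pytest.approx(_binom_tail(10, 20), abs=1e-12)


def test_mcnemar_one_sided_extreme():
    y = np.zeros(30, dtype=int)
    y[::2] = 1
    pa = y.copy()
    pb = y.copy()
    pb[:15] = 1 - pb[:15]
    p, b, c = M.mcnemar_test(y, pa, pb)
    assert (b, c) == (15, 0)
    assert p == pytest.approx(2.0**-15, abs=1e-12)
    assert p < 0.001
    p_swapped, b2, c2 = M.mcnemar_test(y, pb, pa)
    assert (b2, c2) == (0, 15)
    # opposite tail: P(X >= 0) = 1 for the reversed alternative
    assert p_swapped == pytest.approx(_binom_tail(0, 15), abs=1e-12)


@settings(derandomize=True, max_examples=25, deadline=None)
@given(b=st.integers(0, 12), c=st.integers(0, 12))
def test_mcnemar_exact_equals_binomial_sum(b, c):
    if b + c == 0:
        return
    y = np.zeros(b + c + 4, dtype=int)
    y[: (b + c + 4) // 2] = 1
    pa = y.copy()
    pb = y.copy()
    pb[:b] = 1 - pb[:b]
    pa[b : b + c] = 1 - pa[b : b + c]
    p, bb, cc = M.mcnemar_test(y, pa, pb)
    assert (bb, cc) == (b, c)
    assert p == pytest.approx(_binom_tail(b, b + c), abs=1e-12)


def test_mcnemar_chi2_branch_matches_statsmodels():
    from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar

    y = np.zeros(200, dtype=int)
    y[::2] = 1
    pa, pb = y.copy(), y.copy()
    pa[:20] = 1 - pa[:20]
    pb[100:140] = 1 - pb[100:140]
    p, b, c = M.mcnemar_test(y, pa, pb)
    assert b + c >= 25
    sm_p = sm_mcnemar([[0, b], [c, 0]], exact=False, correction=True).pvalue
    assert p == pytest.approx(sm_p / 2.0, abs=1e-10)  # one-sided half


def test_mcnemar_no_discordance():
    y = np.array([0, 1, 0, 1])
    with pytest.warns(UserWarning):
        p, b, c = M.mcnemar_test(y, y, y)
    assert p == 1.0 and b == c == 0


# ---------------------------------------------------------------------------
# AUC
# ---------------------------------------------------------------------------


def test_auc_examples():
    y = np.array([0, 0, 1, 1])
    assert M.auc([0.1, 0.2, 0.8, 0.9], y) == 100.0
    assert M.auc([0.5, 0.5, 0.5, 0.5], y) == 50.0
    with pytest.raises(ValueError):
        M.auc([0.1, 0.2], [1, 1])


@settings(derandomize=True, max_examples=25, deadline=None)
@given(seed=st.integers(0, 10_000))
def test_auc_matches_pairwise_oracle(seed):
    rng = np.random.default_rng(seed)
    scores = rng.uniform(0, 1, 20).round(2)  # ties likely
    y = rng.integers(0, 2, 20)
    if y.min() == y.max():
        y[0] = 1 - y[0]
    pos = scores[y == 1]
    neg = scores[y == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    oracle = 100.0 * wins / (len(pos) * len(neg))
    assert M.auc(scores, y) == pytest.approx(oracle, abs=1e-10)
    assert M.auc(scores, y) == pytest.approx(100 * roc_auc_score(y, scores), abs=1e-10)


# ---------------------------------------------------------------------------
# Davies-Bouldin and separability
# ---------------------------------------------------------------------------


def _db_oracle(points, labels):
    uniq = np.unique(labels)
    cents = {u: points[labels == u].mean(axis=0) for u in uniq}
    disp = {u: np.mean(np.linalg.norm(points[labels == u] - cents[u], axis=1)) for u in uniq}
    total = 0.0
    for i in uniq:
        total += max(
            (disp[i] + disp[j]) / np.linalg.norm(cents[i] - cents[j]) for j in uniq if j != i
        )
    return total / len(uniq)


def test_db_two_tight_distant_clusters():
    rng = np.random.default_rng(0)
    pts = np.concatenate([rng.normal(0, 0.01, (30, 2)), rng.normal(100, 0.01, (30, 2))])
    labels = np.array([0] * 30 + [1] * 30)
    assert M.davies_bouldin(pts, labels) < 0.01


def test_db_scale_invariance_and_oracle():
    rng = np.random.default_rng(1)
    pts = rng.standard_normal((30, 2))
    labels = rng.integers(0, 3, 30)
    v = M.davies_bouldin(pts, labels)
    assert v == pytest.approx(M.davies_bouldin(pts * 7.3, labels))
    assert v == pytest.approx(_db_oracle(pts, labels), abs=1e-10)
    assert v == pytest.approx(davies_bouldin_score(pts, labels), abs=1e-8)


def test_db_coincident_centroids():
    pts = np.array([[0.0, 0], [1, 1], [0, 0], [1, 1]])
    with pytest.warns(UserWarning):
        assert M.davies_bouldin(pts, np.array([0, 0, 1, 1])) == np.inf
    with pytest.raises(ValueError):
        M.davies_bouldin(pts, np.zeros(4))


def test_separability_identical_feature_sets():
    rng = np.random.default_rng(2)
    F = rng.standard_normal((80, 6))
    F[:40] += 4.0
    labels = np.array([1] * 40 + [0] * 40)
    out = M.separability_experiment(F, F, labels, B=50, seed=3)
    assert out["p_value"] >= 0.95  # identical sets: lstm never better
    assert out["db_classical_sd"] >= 0 and out["db_lstm_sd"] >= 0


def test_separability_constructed_contrast():
    """Well-separated learned features vs pure-noise classical features."""
    rng = np.random.default_rng(4)
    n = 120
    labels = np.array([1] * 40 + [0] * 80)
    lstm = rng.standard_normal((n, 8)) * 0.3
    lstm[labels == 1] += 5.0
    classical = rng.standard_normal((n, 10))
    out = M.separability_experiment(classical, lstm, labels, B=100, seed=5)
    assert out["db_lstm_mean"] < out["db_classical_mean"]
    assert out["p_value"] < 0.05
    with pytest.raises(ValueError):
        M.separability_experiment(classical, lstm, labels, B=1)


# ---------------------------------------------------------------------------
# AHA compliance and error reduction
# ---------------------------------------------------------------------------


def test_aha_check():
    assert M.aha_check(99.2, 96.7) is True
    assert M.aha_check(90.0, 95.0) is True  # inclusive bounds
    assert M.aha_check(89.9, 99.0) is False
    assert M.aha_check(95.0, 94.9) is False
    with pytest.raises(ValueError):
        M.aha_check(-1, 50)


def test_error_reduction():
    assert M.error_reduction(96.1, 97.5) == pytest.approx(35.9, abs=0.05)
    assert M.error_reduction(96.1, 97.5) > 35.0
    assert M.error_reduction(88.0, 88.0) == 0.0
    assert M.error_reduction(90.0, 100.0) == 100.0
    with pytest.raises(Exception):
        M.error_reduction(100.0, 100.0)


# ---------------------------------------------------------------------------
# LSTM feature ranking (uses the trained separable-cohort model)
# ---------------------------------------------------------------------------


def test_rank_lstm_features_contract(separable_training):
    segs, fitted, _ = separable_training
    # alternate blocks of four so both classes land on the test side
    test = segs.subset((np.arange(len(segs)) // 4) % 2 == 1)
    table = M.rank_lstm_features(fitted, test).table
    assert len(table) == 20
    assert table["auc_complete"].is_monotonic_decreasing
    assert table["auc_complete"].between(0, 100).all()
    assert set(table["feature"]) == {f"lstm_{j}" for j in range(1, 21)}
    assert table["auc_complete"].iloc[0] >= 90.0  # separable construction
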