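"""Evaluation statistics for shock-advice algorithms.

Balanced accuracy (the unweighted mean of sensitivity and specificity)
is the headline ranking metric because the rhythm classes are strongly
imbalanced (roughly 4 nonshockable segments per shockable one).  The
module also provides the McNemar paired comparison, rank-based AUC for
per-feature discriminability, Davies-Bouldin cluster separability on
t-SNE embeddings with bootstrap confidence, the AHA minimum-performance
check (Se >= 90, Sp >= 95), and error-reduction arithmetic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.manifold import TSNE

from .errors import VfdetectError


@dataclass(frozen=True)
class MetricsReport:
    """Confusion counts and the derived percentages for one test set."""

    tp: int
    fp: int
    tn: int
    fn: int
    se: float
    sp: float
    ppv: float  # NaN when undefined
    npv: float
    acc: float
    bac: float
    tag: str = ""
    L: float | None = None

    def to_series(self) -> pd.Series:
        return pd.Series(
            {
                "tag": self.tag,
                "L": self.L,
                "TP": self.tp,
                "FP": self.fp,
                "TN": self.tn,
                "FN": self.fn,
                "Se": self.se,
                "Sp": self.sp,
                "PPV": self.ppv,
                "NPV": self.npv,
                "Acc": self.acc,
                "BAC": self.bac,
            }
        )


def confusion_metrics(y, y_pred, tag: str = "", L: float | None = None) -> MetricsReport:
    """Se/Sp/PPV/NPV/Acc/BAC (percent) from binary labels and decisions.

    Positive class = shockable (1).  Undefined predictive values (zero
    denominator) are reported as NaN with a warning rather than 0.
    """
    y = np.asarray(y).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    if len(y) == 0 or len(y) != len(y_pred):
        raise ValueError("need equal-length, non-empty label/decision vectors")
    if y.min() == y.max():
        raise ValueError("both classes must be present in y")
    tp = int(np.sum((y == 1) & (y_pred == 1)))
    fn = int(np.sum((y == 1) & (y_pred == 0)))
    tn = int(np.sum((y == 0) & (y_pred == 0)))
    fp = int(np.sum((y == 0) & (y_pred == 1)))
    se = 100.0 * tp / (tp + fn)
    sp = 100.0 * tn / (tn + fp)
    if tp + fp == 0:
        warnings.warn("PPV undefined (no positive predictions)")
        ppv = float("nan")
    else:
        ppv = 100.0 * tp / (tp + fp)
    if tn + fn == 0:
        warnings.warn("NPV undefined (no negative predictions)")
        npv = float("nan")
    else:
        npv = 100.0 * tn / (tn + fn)
    acc = 100.0 * (tp + tn) / len(y)
    return MetricsReport(
        tp=tp, fp=fp, tn=tn, fn=fn, se=se, sp=sp, ppv=ppv, npv=npv, acc=acc,
        bac=(se + sp) / 2.0, tag=tag, L=L,
    )


def mcnemar_test(y, pred_a, pred_b) -> tuple[float, int, int]:
    """One-sided paired comparison of two classifiers on the same instances.

    b counts instances A got right and B wrong, c the converse.  Small
    discordance (b + c < 25) uses the exact binomial tail P(X >= b | n=b+c,
    1/2); otherwise the continuity-corrected chi-square, halved for the
    one-sided alternative that A is more accurate than B.
    """
    y, pa, pb = (np.asarray(a).astype(int) for a in (y, pred_a, pred_b))
    if not (len(y) == len(pa) == len(pb)):
        raise ValueError("length mismatch")
    a_right, b_right = pa == y, pb == y
    b = int(np.sum(a_right & ~b_right))
    c = int(np.sum(~a_right & b_right))
    n = b + c
    if n == 0:
        warnings.warn("no discordant pairs; p = 1")
        return 1.0, b, c
    if n < 25:
        p = float(stats.binom.sf(b - 1, n, 0.5))
    else:
        chi2 = (abs(b - c) - 1.0) ** 2 / n
        p = float(stats.chi2.sf(chi2, df=1) / 2.0)
        if b < c:  # observed direction opposes the alternative
            p = 1.0 - p
    return min(max(p, 0.0), 1.0), b, c


def auc(scores, y) -> float:
    """Rank-based (Mann-Whitney) area under the ROC curve, in percent."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y).astype(int)
    n_pos = int(np.sum(y == 1))
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes required for AUC")
    ranks = stats.rankdata(scores)
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return 100.0 * u / (n_pos * n_neg)


@dataclass
class FeatureAucTable:
    """Per-feature AUCs on the complete test set and its subsets, sorted
    descending by the complete-set AUC."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.table["auc_complete"].is_monotonic_decreasing:
            raise ValueError("table must be sorted by descending complete-set AUC")

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def rank_lstm_features(model, test_set, subsets: dict[str, np.ndarray] | None = None) -> FeatureAucTable:
    """AUC-rank the learned LSTM features on the test set.

    No training happens here: the trained model computes its Q features
    for each test segment, and each feature gets one AUC per subset (the
    complete set always; named subsets, e.g. public vs OHCA, when masks
    are given).
    """
    from .net import lstm_feature_matrix

    if len(test_set) == 0:
        raise ValueError("empty test set")
    F = lstm_feature_matrix(model, test_set)
    y = test_set.labels()
    q = F.shape[1]
    rows = []
    for j in range(q):
        row = {"feature": f"lstm_{j + 1}", "auc_complete": auc(F[:, j], y)}
        for name, mask in (subsets or {}).items():
            mask = np.asarray(mask)
            if mask.any() and len(np.unique(y[mask])) == 2:
                row[f"auc_{name}"] = auc(F[mask, j], y[mask])
            else:
                row[f"auc_{name}"] = float("nan")
        rows.append(row)
    df = pd.DataFrame(rows).sort_values("auc_complete", ascending=False, kind="mergesort")
    return FeatureAucTable(df.reset_index(drop=True))


def davies_bouldin(points, labels) -> float:
    """Davies-Bouldin index: mean over clusters of the worst-pair ratio
    (s_i + s_j) / d_ij with centroid distances d and mean dispersions s.
    Lower is better separated.  Coincident centroids give inf (flagged)."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("need at least 2 clusters")
    centroids = np.stack([points[labels == u].mean(axis=0) for u in uniq])
    disp = np.array(
        [np.mean(np.linalg.norm(points[labels == u] - centroids[i], axis=1)) for i, u in enumerate(uniq)]
    )
    k = len(uniq)
    worst = np.zeros(k)
    for i in range(k):
        ratios = []
        for j in range(k):
            if i == j:
                continue
            d = np.linalg.norm(centroids[i] - centroids[j])
            if d == 0:
                warnings.warn("coincident cluster centroids; index is infinite")
                return float("inf")
            ratios.append((disp[i] + disp[j]) / d)
        worst[i] = max(ratios)
    return float(worst.mean())


def tsne_embed(features: np.ndarray, seed: int = 0, perplexity: float = 30.0) -> np.ndarray:
    """Barnes-Hut t-SNE to 2-D (standardized input; seed-controlled)."""
    X = np.asarray(features, dtype=float)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Xs = (X - X.mean(axis=0)) / sd
    perplexity = min(perplexity, (len(X) - 1) / 3.0)
    ts = TSNE(
        n_components=2,
        method="barnes_hut",
        angle=0.5,
        perplexity=perplexity,
        max_iter=1000,
        init="pca",
        random_state=int(seed) % (2**31),
    )
    return ts.fit_transform(Xs)


def separability_experiment(
    classical_features: np.ndarray,
    lstm_features: np.ndarray,
    labels: np.ndarray,
    B: int = 1000,
    seed: int = 0,
) -> dict[str, float]:
    """Compare class separability of the two feature sets.

    Each feature set is embedded to 2-D with Barnes-Hut t-SNE; the
    Davies-Bouldin index of the shock/no-shock clusters is computed on B
    paired bootstrap resamples of the embedded points.  The p-value is
    the fraction of replicas where the learned features are *not* better
    (db_lstm >= db_classical).
    """
    if B < 2:
        raise ValueError("need at least 2 bootstrap replicas")
    labels = np.asarray(labels)
    if len(classical_features) != len(lstm_features) or len(labels) != len(lstm_features):
        raise ValueError("feature sets and labels must be matched instance-wise")
    emb_c = tsne_embed(classical_features, seed=seed)
    emb_l = tsne_embed(lstm_features, seed=seed + 1)
    rng = np.random.default_rng(seed)
    n = len(labels)
    db_c = np.empty(B)
    db_l = np.empty(B)
    for i in range(B):
        idx = rng.integers(0, n, size=n)
        while len(np.unique(labels[idx])) < 2:
            idx = rng.integers(0, n, size=n)
        db_c[i] = davies_bouldin(emb_c[idx], labels[idx])
        db_l[i] = davies_bouldin(emb_l[idx], labels[idx])
    return {
        "db_classical_mean": float(db_c.mean()),
        "db_classical_sd": float(db_c.std(ddof=1)),
        "db_lstm_mean": float(db_l.mean()),
        "db_lstm_sd": float(db_l.std(ddof=1)),
        "p_value": float(np.mean(db_l >= db_c)),
    }


def aha_check(se: float, sp: float) -> bool:
    """AHA minimum performance goals: Se >= 90% and Sp >= 95% (inclusive)."""
    if not (0 <= se <= 100 and 0 <= sp <= 100):
        raise ValueError("percentages must lie in [0, 100]")
    return se >= 90.0 and sp >= 95.0


def error_reduction(acc_old: float, acc_new: float) -> float:
    """Percent of the old model's errors corrected by the new model."""
    if acc_old >= 100.0:
        raise VfdetectError("error reduction undefined: baseline already perfect")
    return 100.0 * (acc_new - acc_old) / (100.0 - acc_old)
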