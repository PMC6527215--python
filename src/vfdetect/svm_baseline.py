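"""Gaussian-kernel SVM baselines for the shock/no-shock decision.

Two baselines mirror the classical machine-learning approach: an SVM on
a registry of hand-crafted VF-detection features (amplitude, slope,
spectral and complexity measures), and an SVM fed with the features
learned by the LSTM block of the deep classifier.  Hyperparameters (soft
margin C, kernel width gamma) are found by Bayesian optimization over
the box 1e-3 <= C, gamma <= 2e2 with cross-validated balanced accuracy
as the objective; class imbalance is handled by instance weights that
equalize the total weight of the two classes, and at most 0.5% of
training instances may be discarded as margin outliers.

The quadratic-programming dual is delegated to a standard solver
(sklearn's SVC); the stored model keeps only the support vectors, their
multipliers, the bias and the standardization constants, and the
decision function is re-evaluated here as the explicit kernel sum
sign(sum_i alpha_i y_i exp(-gamma ||x - x_i||^2) + b).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.signal import periodogram
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, Matern
from sklearn.model_selection import GroupKFold, StratifiedKFold
from sklearn.svm import SVC

from .errors import RegistryError
from .segmenter import SegmentSet

HYPER_BOX = (1e-3, 2e2)  # bounds for both C and gamma


@dataclass(frozen=True)
class FeatureVector:
    values: np.ndarray
    feature_names: tuple[str, ...]
    kind: str = "classical"  # "classical" | "lstm"

    def __post_init__(self) -> None:
        if len(self.values) != len(self.feature_names):
            raise ValueError("values/names length mismatch")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("feature names must be unique")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite feature values")


@dataclass
class SvmModel:
    """Support vectors + multipliers + bias + standardization constants."""

    support_vectors: np.ndarray  # (Ns, K) standardized coordinates
    alpha: np.ndarray  # (Ns,) non-negative multipliers
    sv_labels: np.ndarray  # (Ns,) +/-1
    bias: float
    gamma: float
    C: float
    mean: np.ndarray
    scale: np.ndarray

    def standardize(self, X: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(X) - self.mean) / self.scale


def rbf_kernel(x: np.ndarray, x2: np.ndarray, gamma: float) -> float:
    """exp(-gamma ||x - x'||^2); in (0, 1], symmetric."""
    x, x2 = np.asarray(x, dtype=float), np.asarray(x2, dtype=float)
    if x.shape != x2.shape:
        raise ValueError("dimension mismatch")
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    return float(np.exp(-gamma * np.sum((x - x2) ** 2)))


def _class_balance_weights(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y)
    n = len(y)
    n_pos = int(np.sum(y == 1))
    if n_pos in (0, n):
        raise ValueError("both classes required")
    return np.where(y == 1, n / (2.0 * n_pos), n / (2.0 * (n - n_pos)))


def fit_svm(
    X: np.ndarray,
    y: np.ndarray,
    C: float = 1.0,
    gamma: float | str = "scale",
    weights: np.ndarray | None = None,
) -> SvmModel:
    """Weighted soft-margin RBF SVM.  y in {-1, +1}; features standardized
    with training statistics before solving the dual."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0
    Xs = (X - mean) / scale
    if gamma == "scale":
        gamma = 1.0 / X.shape[1]
    if weights is None:
        weights = _class_balance_weights(y)
    svc = SVC(C=C, gamma=gamma, kernel="rbf")
    svc.fit(Xs, y, sample_weight=weights)
    dual = svc.dual_coef_[0]  # alpha_i * y_i
    return SvmModel(
        support_vectors=svc.support_vectors_.copy(),
        alpha=np.abs(dual),
        sv_labels=np.sign(dual).astype(int),
        bias=float(svc.intercept_[0]),
        gamma=float(gamma),
        C=float(C),
        mean=mean,
        scale=scale,
    )


def decision_values(model: SvmModel, X: np.ndarray) -> np.ndarray:
    """Explicit kernel-sum decision values on raw (unstandardized) inputs."""
    Xs = model.standardize(X)
    d2 = ((Xs[:, None, :] - model.support_vectors[None, :, :]) ** 2).sum(axis=2)
    return np.exp(-model.gamma * d2) @ (model.alpha * model.sv_labels) + model.bias


def svm_decide(model: SvmModel, x: np.ndarray) -> int:
    """sign of the kernel sum; exact zero maps to +1 (shock on ties)."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or len(x) != model.support_vectors.shape[1]:
        raise ValueError("dimension mismatch")
    val = decision_values(model, x[None, :])[0]
    return 1 if val >= 0 else -1


# ---------------------------------------------------------------------------
# Bayesian hyperparameter search (GP surrogate, expected improvement)
# ---------------------------------------------------------------------------


def _cv_bac(X, y, C, gamma, groups, n_splits, seed) -> float:
    y = np.asarray(y)
    if groups is not None:
        splitter = GroupKFold(n_splits=min(n_splits, len(np.unique(groups))))
        folds = splitter.split(X, y, groups)
    else:
        splitter = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
        folds = splitter.split(X, y)
    bacs = []
    for tr, te in folds:
        if len(np.unique(y[tr])) < 2 or len(np.unique(y[te])) < 2:
            continue
        model = fit_svm(X[tr], y[tr], C=C, gamma=gamma)
        pred = np.where(decision_values(model, X[te]) >= 0, 1, -1)
        se = np.mean(pred[y[te] == 1] == 1)
        sp = np.mean(pred[y[te] == -1] == -1)
        bacs.append((se + sp) / 2.0)
    return float(np.mean(bacs)) if bacs else 0.5


def tune_hyperparams(
    X: np.ndarray,
    y: np.ndarray,
    seed: int = 0,
    groups: np.ndarray | None = None,
    n_calls: int = 60,
    n_initial: int = 10,
    n_splits: int = 5,
) -> tuple[float, float]:
    """Search (C, gamma) in the log-uniform box by GP expected improvement.

    The objective is k-fold (patient-grouped when groups are given)
    cross-validated balanced accuracy.  Deterministic given the seed.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    rng = np.random.default_rng(seed)
    lo, hi = np.log10(HYPER_BOX[0]), np.log10(HYPER_BOX[1])
    pts = list(rng.uniform(lo, hi, size=(n_initial, 2)))
    vals = [_cv_bac(X, y, 10.0 ** p[0], 10.0 ** p[1], groups, n_splits, seed) for p in pts]
    kernel = ConstantKernel(1.0) * Matern(length_scale=[1.0, 1.0], nu=2.5)
    for _ in range(max(0, n_calls - n_initial)):
        gp = GaussianProcessRegressor(
            kernel=kernel, alpha=1e-4, normalize_y=True, random_state=int(seed) % (2**31)
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            gp.fit(np.array(pts), np.array(vals))
        cand = rng.uniform(lo, hi, size=(512, 2))
        mu, sd = gp.predict(cand, return_std=True)
        best = max(vals)
        sd = np.maximum(sd, 1e-12)
        z = (mu - best) / sd
        ei = (mu - best) * stats.norm.cdf(z) + sd * stats.norm.pdf(z)
        nxt = cand[int(np.argmax(ei))]
        pts.append(nxt)
        vals.append(_cv_bac(X, y, 10.0 ** nxt[0], 10.0 ** nxt[1], groups, n_splits, seed))
    vals_arr = np.array(vals)
    if np.allclose(vals_arr, vals_arr[0]):
        center = 10.0 ** ((lo + hi) / 2.0)
        warnings.warn("degenerate (constant) tuning objective; returning box center")
        return center, center
    best_pt = pts[int(np.argmax(vals_arr))]
    return float(10.0 ** best_pt[0]), float(10.0 ** best_pt[1])


def trim_outliers(
    X: np.ndarray, y: np.ndarray, frac: float = 0.005, C: float = 1.0, gamma: float | str = "scale"
) -> tuple[np.ndarray, np.ndarray]:
    """Drop up to floor(frac*n) instances with the largest margin violations.

    One-shot: fit once, rank hinge violations max(0, 1 - y*f(x)), remove
    the worst offenders only (clean separable data loses nothing).
    """
    if not 0 <= frac < 0.05:
        raise ValueError("frac must lie in [0, 0.05)")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    k = int(np.floor(frac * len(y)))
    if k == 0:
        return X, y
    model = fit_svm(X, y, C=C, gamma=gamma)
    viol = np.maximum(0.0, 1.0 - y * decision_values(model, X))
    order = np.argsort(-viol)
    drop = [i for i in order[:k] if viol[i] > 1.0]  # misclassified-side violators only
    keep = np.setdiff1d(np.arange(len(y)), drop)
    return X[keep], y[keep]


# ---------------------------------------------------------------------------
# Classical VF-detection feature registry
# ---------------------------------------------------------------------------


def _dominant_frequency(x, fs):
    f, p = periodogram(x, fs=fs)
    band = (f >= 0.5) & (f <= 30.0)
    if not band.any() or p[band].max() == 0:
        return 0.0
    return float(f[band][np.argmax(p[band])])


def _spectral_flatness(x, fs):
    _, p = periodogram(x, fs=fs)
    p = p[1:]
    p = p[p > 0]
    if len(p) == 0:
        return 0.0
    return float(np.exp(np.mean(np.log(p))) / np.mean(p))


def _band_power_ratio(x, fs):
    f, p = periodogram(x, fs=fs)
    low = p[(f >= 0.5) & (f < 9.0)].sum()
    high = p[(f >= 9.0) & (f <= 30.0)].sum()
    return float(low / high) if high > 0 else 0.0


def _threshold_crossing_rate(x, fs):
    """Crossings per second of +/- 20% of the peak deviation."""
    peak = np.abs(x - np.median(x)).max()
    if peak == 0:
        return 0.0
    s = np.sign(x - np.median(x) - 0.2 * peak)
    s = s[s != 0]
    return float(np.sum(np.abs(np.diff(s)) > 0) / (len(x) / fs))


def _sample_entropy(x, fs, m: int = 2, r_frac: float = 0.2, max_n: int = 500):
    """Sample-entropy-style complexity on a decimated copy (cost control)."""
    x = np.asarray(x, dtype=float)
    step = max(1, len(x) // max_n)
    x = x[::step]
    n = len(x)
    sd = x.std()
    if sd == 0 or n <= m + 1:
        return 0.0
    r = r_frac * sd
    def _count(mm):
        templ = np.lib.stride_tricks.sliding_window_view(x, mm)
        d = np.abs(templ[:, None, :] - templ[None, :, :]).max(axis=2)
        mask = (d <= r) & ~np.eye(len(templ), dtype=bool)
        return mask.sum()
    b = _count(m)
    a = _count(m + 1)
    if a == 0 or b == 0:
        return float(np.log(n))
    return float(-np.log(a / b))


FEATURE_REGISTRY = {
    "mean_abs_slope": lambda x, fs: float(np.mean(np.abs(np.diff(x))) * fs),
    "dominant_frequency": _dominant_frequency,
    "spectral_flatness": _spectral_flatness,
    "band_power_ratio": _band_power_ratio,
    "threshold_crossing_rate": _threshold_crossing_rate,
    "peak_to_peak": lambda x, fs: float(x.max() - x.min()),
    "kurtosis": lambda x, fs: _finite(stats.kurtosis(x)) if x.std() > 1e-9 else 0.0,
    "sample_entropy": _sample_entropy,
    "rms_amplitude": lambda x, fs: float(np.sqrt(np.mean(x**2))),
    "spectral_centroid": lambda x, fs: _spectral_centroid(x, fs),
}


def _finite(v) -> float:
    return float(v) if np.isfinite(v) else 0.0


def _spectral_centroid(x, fs):
    f, p = periodogram(x, fs=fs)
    tot = p[1:].sum()
    return float((f[1:] * p[1:]).sum() / tot) if tot > 0 else 0.0


def compute_classical_features(
    seg, fs: float, registry: list[str] | None = None
) -> FeatureVector:
    """Evaluate the requested registry features on one preprocessed segment."""
    x = np.asarray(seg.samples if hasattr(seg, "samples") else seg, dtype=float)
    names = tuple(registry) if registry is not None else tuple(FEATURE_REGISTRY)
    vals = []
    for name in names:
        if name not in FEATURE_REGISTRY:
            raise RegistryError(f"unknown feature {name!r}; registry has {sorted(FEATURE_REGISTRY)}")
        vals.append(FEATURE_REGISTRY[name](x, fs))
    return FeatureVector(values=np.array(vals), feature_names=names, kind="classical")


def classical_feature_matrix(segments: SegmentSet, registry: list[str] | None = None) -> np.ndarray:
    return np.stack(
        [compute_classical_features(s, segments.fs, registry).values for s in segments.segments]
    )


# ---------------------------------------------------------------------------
# SVM on LSTM features
# ---------------------------------------------------------------------------


def select_lstm_subset(F_train: np.ndarray, y_train: np.ndarray, k: int, names=None) -> list[int]:
    """Greedy forward selection of k features scored by an LDA classifier
    (training-set accuracy with class-balanced weighting)."""
    n_feat = F_train.shape[1]
    if not 1 <= k <= n_feat:
        raise ValueError(f"k must lie in [1, {n_feat}]")
    chosen: list[int] = []
    remaining = list(range(n_feat))
    w = _class_balance_weights(y_train)
    while len(chosen) < k:
        best_j, best_score = remaining[0], -np.inf
        for j in remaining:
            cols = chosen + [j]
            lda = LinearDiscriminantAnalysis()
            lda.fit(F_train[:, cols], y_train)
            score = np.average(lda.predict(F_train[:, cols]) == y_train, weights=w)
            if score > best_score + 1e-12:
                best_j, best_score = j, score
        chosen.append(best_j)
        remaining.remove(best_j)
    return chosen


def svm_on_lstm_features(
    trained_net,
    train_set: SegmentSet,
    test_set: SegmentSet,
    k: int,
    seed: int = 0,
    tune: bool = False,
):
    """Fit an SVM on the best k LSTM features (LDA-selected on training data)
    and evaluate on the test set.  Returns (MetricsReport, selected indices)."""
    from . import metrics as _metrics
    from .net import lstm_feature_matrix

    F_tr = lstm_feature_matrix(trained_net, train_set)
    F_te = lstm_feature_matrix(trained_net, test_set)
    y_tr = np.where(train_set.labels() == 1, 1, -1)
    y_te = test_set.labels()
    cols = select_lstm_subset(F_tr, y_tr, k)
    if tune:
        C, gamma = tune_hyperparams(F_tr[:, cols], y_tr, seed=seed, n_calls=20, n_initial=8)
    else:
        C, gamma = 1.0, 1.0 / len(cols)
    model = fit_svm(F_tr[:, cols], y_tr, C=C, gamma=gamma)
    pred = (decision_values(model, F_te[:, cols]) >= 0).astype(int)
    report = _metrics.confusion_metrics(y_te, pred, tag=f"svm_lstm_k{k}", L=test_set.L)
    return report, cols
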