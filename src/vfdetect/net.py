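"""Mixed 1D-CNN + LSTM shock/no-shock classifier, built directly in NumPy.

The architecture has three stages.  A convolutional block (two sub-blocks
of J=32 filters of size M=3, ReLU, and max-pooling of size K=7) turns the
N-sample ECG segment into a time-compressed feature map.  An LSTM with
Q=20 units integrates the long- and short-range temporal structure of
that map, and its final hidden state feeds a dense sigmoid head that
outputs p_Sh, the probability of a shockable rhythm.  Training minimizes
a class-weighted binary cross-entropy with mini-batch stochastic gradient
descent and Nesterov momentum; the decision threshold is chosen to
maximize the balanced accuracy of the training set.

Everything — forward passes, backpropagation (including truncated-free
BPTT through the LSTM), and the optimizer — is implemented here so that
each piece can be checked against naive loop oracles.

Layer lengths follow the valid-convolution recurrence

    N_l = floor((N_{l-1} + 2p - M) / s) + 1

with padding p = 0, stride s = 1 for convolutions and s = K for pooling,
so an 8-s segment at 250 Hz (N = 2000) compresses to a 40-step sequence
entering the LSTM.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .errors import ArchitectureError, FeatureError, TrainingError, ThresholdError
from .segmenter import Segment, SegmentSet

# ---------------------------------------------------------------------------
# Specifications
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NetSpec:
    """Architecture hyperparameters.

    conv_blocks: one (n_filters J, kernel M, pool K) triple per sub-block.
    lstm_units: Q; 0 disables the recurrent block (CNN-only models flatten
    the feature map instead).  dense_layers ends in the single sigmoid unit.
    """

    conv_blocks: tuple[tuple[int, int, int], ...]
    lstm_units: int = 20
    dense_layers: tuple[int, ...] = (1,)
    padding: int = 0
    conv_stride: int = 1

    def __post_init__(self) -> None:
        if not self.conv_blocks:
            raise ValueError("need at least one convolutional block")
        for j, m, k in self.conv_blocks:
            if min(j, m, k) < 1:
                raise ValueError("conv block sizes must be positive")
        if self.lstm_units < 0:
            raise ValueError("lstm_units must be >= 0")
        if not self.dense_layers or self.dense_layers[-1] != 1:
            raise ValueError("dense_layers must end in the single sigmoid unit")


def proposed_spec(lstm_units: int = 20) -> NetSpec:
    """The mixed CNN+LSTM architecture: two (32, 3, 7) sub-blocks, Q units."""
    return NetSpec(conv_blocks=((32, 3, 7), (32, 3, 7)), lstm_units=lstm_units, dense_layers=(1,))


_VARIANTS = {
    "kiranyaz": NetSpec(((32, 15, 6), (16, 15, 6)), 0, (1,)),
    "zubair": NetSpec(((32, 5, 2), (16, 5, 2), (8, 5, 2)), 0, (1,)),
    "acharya": NetSpec(((3, 5, 2), (5, 5, 2), (10, 5, 2), (10, 4, 2)), 0, (32, 1)),
}


def build_variant(name: str) -> NetSpec:
    """CNN-only comparison architectures (Kiranyaz / Zubair / Acharya)."""
    try:
        return _VARIANTS[name]
    except KeyError:
        raise ValueError(f"unknown variant {name!r}; choose from {sorted(_VARIANTS)}") from None


@dataclass(frozen=True)
class TrainConfig:
    """SGD hyperparameters (Nesterov momentum, per-update lr decay)."""

    lr: float = 1e-3
    lr_decay: float = 1e-6
    momentum: float = 0.9
    epochs: int = 600
    batch_size: int = 256
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lr <= 0 or self.epochs < 1 or self.batch_size < 1:
            raise ValueError("invalid training configuration")


@dataclass
class FittedClassifier:
    """Architecture + parameters + decision threshold + training log."""

    spec: NetSpec
    params: dict[str, np.ndarray]
    input_len: int
    fs: float
    theta: float | None = None
    train_log: list[float] = field(default_factory=list)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return forward(self.spec, self.params, np.atleast_2d(X))[0]

    def __call__(self, seg: Segment):
        return predict(self, seg)


# ---------------------------------------------------------------------------
# Shape arithmetic
# ---------------------------------------------------------------------------


def conv_output_length(n_in: int, m: int, s: int = 1, p: int = 0) -> int:
    """Valid conv/pool length recurrence: floor((N + 2p - M)/s) + 1."""
    if s < 1:
        raise ValueError("stride must be >= 1")
    n_out = (n_in + 2 * p - m) // s + 1
    if n_out < 1:
        raise ArchitectureError(f"layer (M={m}, s={s}) collapses length {n_in} to {n_out}")
    return n_out


def phase_lengths(spec: NetSpec, n_in: int) -> list[int]:
    """Temporal length after each conv and pool phase, starting from n_in."""
    lengths = []
    n = n_in
    for li, (_, m, k) in enumerate(spec.conv_blocks):
        try:
            n = conv_output_length(n, m, spec.conv_stride, spec.padding)
            lengths.append(n)
            n = conv_output_length(n, k, k, 0)
            lengths.append(n)
        except ArchitectureError as exc:
            raise ArchitectureError(f"conv block {li}: {exc}") from None
    return lengths


def lstm_sequence_length(spec: NetSpec, n_in: int) -> int:
    """Length of the feature-map sequence entering the recurrent block."""
    return phase_lengths(spec, n_in)[-1]


# ---------------------------------------------------------------------------
# Initialization
# ---------------------------------------------------------------------------


def _orthogonal(rng: np.random.Generator, n: int) -> np.ndarray:
    q, r = np.linalg.qr(rng.standard_normal((n, n)))
    return q * np.sign(np.diag(r))


def init_params(spec: NetSpec, n_in: int, seed: int) -> dict[str, np.ndarray]:
    """Fan-in-scaled uniform conv/dense weights, orthogonal LSTM recurrence,
    zero biases except the LSTM forget gate (bias 1)."""
    rng = np.random.default_rng(seed)
    params: dict[str, np.ndarray] = {}
    c_in = 1
    for li, (j, m, _) in enumerate(spec.conv_blocks):
        lim = np.sqrt(6.0 / (c_in * m))
        params[f"conv{li}_W"] = rng.uniform(-lim, lim, size=(j, c_in, m))
        params[f"conv{li}_b"] = np.zeros(j)
        c_in = j
    lengths = phase_lengths(spec, n_in)
    t_last = lengths[-1]
    if spec.lstm_units > 0:
        q = spec.lstm_units
        for gate in "fioc":
            lim = np.sqrt(6.0 / (c_in + q))
            params[f"lstm_W{gate}"] = rng.uniform(-lim, lim, size=(q, c_in))
            params[f"lstm_R{gate}"] = _orthogonal(rng, q)
            params[f"lstm_b{gate}"] = np.ones(q) if gate == "f" else np.zeros(q)
        d_in = q
    else:
        d_in = t_last * c_in
    for di, width in enumerate(spec.dense_layers):
        lim = np.sqrt(6.0 / d_in)
        params[f"dense{di}_W"] = rng.uniform(-lim, lim, size=(d_in, width))
        params[f"dense{di}_b"] = np.zeros(width)
        d_in = width
    return params


def build_network(spec: NetSpec, L: float, fs: float, seed: int = 0) -> FittedClassifier:
    """Instantiate an untrained classifier for L-second segments at fs Hz."""
    n_in = int(round(L * fs))
    phase_lengths(spec, n_in)  # raises ArchitectureError naming the layer
    return FittedClassifier(spec=spec, params=init_params(spec, n_in, seed), input_len=n_in, fs=fs)


# ---------------------------------------------------------------------------
# Forward primitives (each checkable against a naive loop oracle)
# ---------------------------------------------------------------------------


def conv1d_relu(x: np.ndarray, W: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Valid cross-correlation + ReLU.  x: (T, C) or (B, T, C); W: (J, C, M)."""
    single = x.ndim == 2
    A = x[None] if single else x
    if A.shape[2] != W.shape[1]:
        raise ArchitectureError(f"input channels {A.shape[2]} != filter channels {W.shape[1]}")
    if A.shape[1] < W.shape[2]:
        raise ArchitectureError("sequence shorter than kernel")
    win = sliding_window_view(A, W.shape[2], axis=1)  # (B, T_out, C, M)
    z = np.einsum("btcm,jcm->btj", win, W) + b
    out = np.maximum(z, 0.0)
    return out[0] if single else out


def maxpool(x: np.ndarray, K: int) -> np.ndarray:
    """Non-overlapping K-block maxima per channel; trailing partial block dropped."""
    if K < 1:
        raise ValueError("pool size must be >= 1")
    single = x.ndim == 2
    A = x[None] if single else x
    B, T, C = A.shape
    if T < K:
        raise ArchitectureError(f"sequence of {T} shorter than pool {K}")
    Tp = T // K
    out = A[:, : Tp * K].reshape(B, Tp, K, C).max(axis=2)
    return out[0] if single else out


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * z))


def lstm_forward(P: np.ndarray, params: dict[str, np.ndarray], prefix: str = "lstm_") -> np.ndarray:
    """Run the gated recurrence over a (T, J) or (B, T, J) sequence.

    Gates use sigmoid activations; the cell state integrates the gated
    input and the hidden state is the output gate times tanh(cell).
    Returns the hidden state at the final step.
    """
    single = P.ndim == 2
    X = P[None] if single else P
    Wf, Wi, Wo, Wc = (params[f"{prefix}W{g}"] for g in "fioc")
    Rf, Ri, Ro, Rc = (params[f"{prefix}R{g}"] for g in "fioc")
    bf, bi, bo, bc = (params[f"{prefix}b{g}"] for g in "fioc")
    if X.shape[2] != Wf.shape[1]:
        raise ArchitectureError(f"LSTM input dim {X.shape[2]} != W columns {Wf.shape[1]}")
    B, T, _ = X.shape
    q = Wf.shape[0]
    h = np.zeros((B, q))
    c = np.zeros((B, q))
    for i in range(T):
        p = X[:, i]
        f = _sigmoid(p @ Wf.T + h @ Rf.T + bf)
        g_in = _sigmoid(p @ Wi.T + h @ Ri.T + bi)
        o = _sigmoid(p @ Wo.T + h @ Ro.T + bo)
        c = f * c + g_in * np.tanh(p @ Wc.T + h @ Rc.T + bc)
        h = o * np.tanh(c)
    return h[0] if single else h


def forward(spec: NetSpec, params: dict[str, np.ndarray], X: np.ndarray, cache: bool = False):
    """Full forward pass.  X: (B, N).  Returns (p_Sh, features, cache)."""
    A = X[:, :, None]  # (B, T, 1)
    caches: dict[str, list] = {"conv": [], "pool": []}
    for li in range(len(spec.conv_blocks)):
        W, b = params[f"conv{li}_W"], params[f"conv{li}_b"]
        win = sliding_window_view(A, W.shape[2], axis=1)
        z = np.einsum("btcm,jcm->btj", win, W) + b
        out = np.maximum(z, 0.0)
        K = spec.conv_blocks[li][2]
        B_, T, C = out.shape
        Tp = T // K
        blocks = out[:, : Tp * K].reshape(B_, Tp, K, C)
        arg = blocks.argmax(axis=2)
        pooled = np.take_along_axis(blocks, arg[:, :, None, :], axis=2)[:, :, 0, :]
        if cache:
            caches["conv"].append((A, win, z))
            caches["pool"].append((out.shape, arg))
        A = pooled
    lstm_cache = None
    if spec.lstm_units > 0:
        feats, lstm_cache = _lstm_forward_cached(A, params)
    else:
        feats = A.reshape(A.shape[0], -1)
    caches["lstm"] = (A, lstm_cache)
    caches["dense"] = []
    H = feats
    for di, width in enumerate(spec.dense_layers):
        zd = H @ params[f"dense{di}_W"] + params[f"dense{di}_b"]
        if di < len(spec.dense_layers) - 1:
            Hn = np.maximum(zd, 0.0)
        else:
            Hn = _sigmoid(zd)
        if cache:
            caches["dense"].append((H, zd))
        H = Hn
    p = H[:, 0]
    return (p, feats, caches) if cache else (p, feats)


def _lstm_forward_cached(P: np.ndarray, params: dict[str, np.ndarray]):
    Wf, Wi, Wo, Wc = (params[f"lstm_W{g}"] for g in "fioc")
    Rf, Ri, Ro, Rc = (params[f"lstm_R{g}"] for g in "fioc")
    bf, bi, bo, bc = (params[f"lstm_b{g}"] for g in "fioc")
    B, T, _ = P.shape
    q = Wf.shape[0]
    h = np.zeros((B, q))
    c = np.zeros((B, q))
    F, I, O, G, Cs, Hs = (np.zeros((T, B, q)) for _ in range(6))
    Cprev = np.zeros((T, B, q))
    Hprev = np.zeros((T, B, q))
    for i in range(T):
        p = P[:, i]
        Hprev[i], Cprev[i] = h, c
        f = _sigmoid(p @ Wf.T + h @ Rf.T + bf)
        gi = _sigmoid(p @ Wi.T + h @ Ri.T + bi)
        o = _sigmoid(p @ Wo.T + h @ Ro.T + bo)
        g = np.tanh(p @ Wc.T + h @ Rc.T + bc)
        c = f * c + gi * g
        h = o * np.tanh(c)
        F[i], I[i], O[i], G[i], Cs[i], Hs[i] = f, gi, o, g, c, h
    return h, (P, F, I, O, G, Cs, Hs, Cprev, Hprev)


# ---------------------------------------------------------------------------
# Loss, class weights, gradients
# ---------------------------------------------------------------------------

_P_CLIP = 1e-7


def weighted_bce_loss(y: np.ndarray, p: np.ndarray, eta: np.ndarray) -> float:
    """Class-weighted binary cross-entropy: -sum_i eta_i [y ln p + (1-y) ln(1-p)].

    Probabilities are clipped to [1e-7, 1 - 1e-7] so the loss stays finite.
    """
    y, p, eta = (np.asarray(a, dtype=float) for a in (y, p, eta))
    if not (len(y) == len(p) == len(eta)):
        raise ValueError("y, p and eta must have equal length")
    pc = np.clip(p, _P_CLIP, 1.0 - _P_CLIP)
    return float(-np.sum(eta * (y * np.log(pc) + (1.0 - y) * np.log1p(-pc))))


def class_weights(labels: np.ndarray) -> np.ndarray:
    """Inverse-prevalence instance weights: eta_i = n / (2 * n_class(i)).

    Both classes then carry equal total weight during optimization.
    """
    y = np.asarray(labels).astype(int)
    n = len(y)
    n_pos = int(y.sum())
    if n_pos == 0 or n_pos == n:
        raise ValueError("class weighting needs both classes present")
    eta = np.where(y == 1, n / (2.0 * n_pos), n / (2.0 * (n - n_pos)))
    return eta


def _backward(spec, params, caches, p, y, eta):
    """Gradients of the batch-mean weighted BCE w.r.t. every parameter."""
    B = len(y)
    grads = {k: np.zeros_like(v) for k, v in params.items()}
    delta = (eta * (p - y) / B)[:, None]  # d(mean loss)/d(logit)
    # dense head (last layer sigmoid, hidden layers ReLU)
    for di in reversed(range(len(spec.dense_layers))):
        H, zd = caches["dense"][di]
        if di < len(spec.dense_layers) - 1:
            delta = delta * (zd > 0)
        grads[f"dense{di}_W"] = H.T @ delta
        grads[f"dense{di}_b"] = delta.sum(axis=0)
        delta = delta @ params[f"dense{di}_W"].T
    A_last, lstm_cache = caches["lstm"]
    if spec.lstm_units > 0:
        dP = _lstm_backward(params, lstm_cache, delta, grads)
    else:
        dP = delta.reshape(A_last.shape)
    # conv blocks in reverse
    for li in reversed(range(len(spec.conv_blocks))):
        out_shape, arg = caches["pool"][li]
        A_in, win, z = caches["conv"][li]
        K = spec.conv_blocks[li][2]
        B_, T, C = out_shape
        Tp = T // K
        dblocks = np.zeros((B_, Tp, K, C))
        np.put_along_axis(dblocks, arg[:, :, None, :], dP[:, :, None, :], axis=2)
        dout = np.zeros((B_, T, C))
        dout[:, : Tp * K] = dblocks.reshape(B_, Tp * K, C)
        dz = dout * (z > 0)
        W = params[f"conv{li}_W"]
        grads[f"conv{li}_W"] = np.einsum("btj,btcm->jcm", dz, win)
        grads[f"conv{li}_b"] = dz.sum(axis=(0, 1))
        M = W.shape[2]
        dA = np.zeros_like(A_in)
        T_out = dz.shape[1]
        for m in range(M):
            dA[:, m : m + T_out, :] += np.einsum("btj,jc->btc", dz, W[:, :, m])
        dP = dA[:, :, :]  # becomes pooled grad of previous block (channels align)
    return grads


def _lstm_backward(params, cache, dh_last, grads):
    P, F, I, O, G, Cs, Hs, Cprev, Hprev = cache
    Wf, Wi, Wo, Wc = (params[f"lstm_W{g}"] for g in "fioc")
    Rf, Ri, Ro, Rc = (params[f"lstm_R{g}"] for g in "fioc")
    B, T, _ = P.shape
    dh = dh_last.copy()
    dc = np.zeros_like(dh)
    dP = np.zeros_like(P)
    for i in reversed(range(T)):
        tc = np.tanh(Cs[i])
        do = dh * tc
        dc = dc + dh * O[i] * (1.0 - tc**2)
        df = dc * Cprev[i]
        dgi = dc * G[i]
        dg = dc * I[i]
        dzf = df * F[i] * (1.0 - F[i])
        dzi = dgi * I[i] * (1.0 - I[i])
        dzo = do * O[i] * (1.0 - O[i])
        dzg = dg * (1.0 - G[i] ** 2)
        p_i, h_prev = P[:, i], Hprev[i]
        for name, dz, Wmat, Rmat in (
            ("f", dzf, Wf, Rf),
            ("i", dzi, Wi, Ri),
            ("o", dzo, Wo, Ro),
            ("c", dzg, Wc, Rc),
        ):
            grads[f"lstm_W{name}"] += dz.T @ p_i
            grads[f"lstm_R{name}"] += dz.T @ h_prev
            grads[f"lstm_b{name}"] += dz.sum(axis=0)
        dP[:, i] = dzf @ Wf + dzi @ Wi + dzo @ Wo + dzg @ Wc
        dh = dzf @ Rf + dzi @ Ri + dzo @ Ro + dzg @ Rc
        dc = dc * F[i]
    return dP


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------


def train(model: FittedClassifier, segments: SegmentSet, cfg: TrainConfig) -> FittedClassifier:
    """Mini-batch SGD with Nesterov momentum and per-update lr decay.

    The learning-rate schedule is lr_t = lr / (1 + decay * t) with t the
    update counter.  After optimization the decision threshold is chosen
    on the *training* predictions by balanced-accuracy maximization.
    """
    X = segments.matrix()
    y = segments.labels().astype(float)
    if X.shape[1] != model.input_len:
        raise ValueError(f"segments of {X.shape[1]} samples; model expects {model.input_len}")
    eta = class_weights(y)
    rng = np.random.default_rng(cfg.seed)
    params = {k: v.copy() for k, v in model.params.items()}
    vel = {k: np.zeros_like(v) for k, v in params.items()}
    mu = cfg.momentum
    t = 0
    log: list[float] = []
    n = len(y)
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            p, _, caches = forward(model.spec, params, X[idx], cache=True)
            grads = _backward(model.spec, params, caches, p, y[idx], eta[idx])
            lr_t = cfg.lr / (1.0 + cfg.lr_decay * t)
            t += 1
            for k in params:
                v_new = mu * vel[k] - lr_t * grads[k]
                params[k] += mu * v_new - lr_t * grads[k]  # Nesterov update
                vel[k] = v_new
            epoch_loss += weighted_bce_loss(y[idx], p, eta[idx])
        mean_loss = epoch_loss / n
        if not np.isfinite(mean_loss):
            raise TrainingError(f"loss diverged (non-finite) at epoch {epoch + 1}")
        log.append(mean_loss)
    p_train, _ = forward(model.spec, params, X)
    theta = select_threshold(p_train, y.astype(int))
    return FittedClassifier(
        spec=model.spec,
        params=params,
        input_len=model.input_len,
        fs=model.fs,
        theta=theta,
        train_log=log,
    )


def select_threshold(p: np.ndarray, y: np.ndarray) -> float:
    """Threshold maximizing balanced accuracy; candidates are 0, 1 and the
    midpoints between consecutive sorted unique probabilities.  Ties break
    toward the smallest threshold."""
    p = np.asarray(p, dtype=float)
    y = np.asarray(y).astype(int)
    if y.min() == y.max():
        raise ThresholdError("threshold selection needs both classes present")
    uniq = np.unique(p)
    cands = np.concatenate(([0.0], (uniq[:-1] + uniq[1:]) / 2.0, [1.0]))
    pred = p[None, :] >= cands[:, None]
    pos, neg = y == 1, y == 0
    se = pred[:, pos].mean(axis=1)
    sp = (~pred[:, neg]).mean(axis=1)
    bac = (se + sp) / 2.0
    best = bac.max()
    return float(cands[np.flatnonzero(bac >= best - 1e-12)[0]])


# ---------------------------------------------------------------------------
# Inference and feature extraction
# ---------------------------------------------------------------------------


def predict(model: FittedClassifier, seg: Segment) -> tuple[float, str]:
    """Return (p_Sh, decision); shock iff p_Sh >= theta (fail-toward-sensitivity)."""
    x = np.asarray(seg.samples, dtype=float)
    if len(x) != model.input_len:
        raise ValueError(f"segment of {len(x)} samples; model expects {model.input_len}")
    p, _ = forward(model.spec, model.params, x[None, :])
    theta = 0.5 if model.theta is None else model.theta
    return float(p[0]), ("shock" if p[0] >= theta else "no_shock")


def decide(model: FittedClassifier, X: np.ndarray) -> np.ndarray:
    theta = 0.5 if model.theta is None else model.theta
    return (model.predict_proba(X) >= theta).astype(int)


def extract_lstm_features(model: FittedClassifier, seg: Segment | np.ndarray) -> np.ndarray:
    """The Q learned features: LSTM hidden state at the final time step."""
    if model.spec.lstm_units == 0:
        raise FeatureError("model has no LSTM block")
    x = seg.samples if isinstance(seg, Segment) else np.asarray(seg, dtype=float)
    X = np.atleast_2d(x)
    _, feats = forward(model.spec, model.params, X)
    return feats[0] if x.ndim == 1 else feats


def lstm_feature_matrix(model: FittedClassifier, segments: SegmentSet, batch: int = 256) -> np.ndarray:
    if model.spec.lstm_units == 0:
        raise FeatureError("model has no LSTM block")
    X = segments.matrix()
    out = [forward(model.spec, model.params, X[i : i + batch])[1] for i in range(0, len(X), batch)]
    return np.concatenate(out, axis=0)


# ---------------------------------------------------------------------------
# Checkpointing
# ---------------------------------------------------------------------------


def save_checkpoint(model: FittedClassifier, path: str | Path) -> None:
    path = Path(path)
    meta = {
        "conv_blocks": [list(b) for b in model.spec.conv_blocks],
        "lstm_units": model.spec.lstm_units,
        "dense_layers": list(model.spec.dense_layers),
        "input_len": model.input_len,
        "fs": model.fs,
        "theta": model.theta,
        "train_log": model.train_log,
    }
    np.savez(path, __meta__=json.dumps(meta), **model.params)


def load_checkpoint(path: str | Path) -> FittedClassifier:
    with np.load(path, allow_pickle=False) as npz:
        meta = json.loads(str(npz["__meta__"]))
        params = {k: npz[k] for k in npz.files if k != "__meta__"}
    spec = NetSpec(
        conv_blocks=tuple(tuple(b) for b in meta["conv_blocks"]),
        lstm_units=meta["lstm_units"],
        dense_layers=tuple(meta["dense_layers"]),
    )
    return FittedClassifier(
        spec=spec,
        params=params,
        input_len=meta["input_len"],
        fs=meta["fs"],
        theta=meta["theta"],
        train_log=list(meta["train_log"]),
    )
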