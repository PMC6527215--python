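"""Network math against naive loop oracles, plus training behavior."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vfdetect import net
from vfdetect.errors import ArchitectureError, FeatureError, ThresholdError
from conftest import make_separable_segments

# ---------------------------------------------------------------------------
# Naive oracles
# ---------------------------------------------------------------------------


def conv_loop(x, W, b):
    """Brute-force valid cross-correlation + ReLU.  x: (T, C); W: (J, C, M)."""
    J, C, M = W.shape
    T = x.shape[0] - M + 1
    out = np.zeros((T, J))
    for t in range(T):
        for j in range(J):
            acc = b[j]
            for c in range(C):
                for m in range(M):
                    acc += W[j, c, m] * x[t + m, c]
            out[t, j] = max(0.0, acc)
    return out


def pool_loop(x, K):
    T, C = x.shape
    out = np.zeros((T // K, C))
    for i in range(T // K):
        for c in range(C):
            out[i, c] = x[i * K : (i + 1) * K, c].max()
    return out


def sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


def lstm_loop(P, params):
    q = params["lstm_Wf"].shape[0]
    h = np.zeros(q)
    c = np.zeros(q)
    for i in range(P.shape[0]):
        p = P[i]
        f = sigmoid(params["lstm_Wf"] @ p + params["lstm_Rf"] @ h + params["lstm_bf"])
        g_in = sigmoid(params["lstm_Wi"] @ p + params["lstm_Ri"] @ h + params["lstm_bi"])
        o = sigmoid(params["lstm_Wo"] @ p + params["lstm_Ro"] @ h + params["lstm_bo"])
        c = f * c + g_in * np.tanh(params["lstm_Wc"] @ p + params["lstm_Rc"] @ h + params["lstm_bc"])
        h = o * np.tanh(c)
    return h


# ---------------------------------------------------------------------------
# Layer-length recurrence
# ---------------------------------------------------------------------------


def test_layer_length_chain_8s():
    """2000 -> 1998 -> 285 -> 283 -> 40 through conv(3,1), pool(7,7) twice."""
    assert net.conv_output_length(2000, 3, 1, 0) == 1998
    assert net.conv_output_length(1998, 7, 7, 0) == 285
    assert net.conv_output_length(285, 3, 1, 0) == 283
    assert net.conv_output_length(283, 7, 7, 0) == 40
    assert net.phase_lengths(net.proposed_spec(), 2000) == [1998, 285, 283, 40]


def test_layer_length_chain_4s():
    assert net.phase_lengths(net.proposed_spec(), 1000) == [998, 142, 140, 20]


@pytest.mark.parametrize("L,expect", [(2, 9), (3, 14), (4, 20), (8, 40)])
def test_lstm_sequence_lengths(L, expect):
    assert net.lstm_sequence_length(net.proposed_spec(), L * 250) == expect


def test_layer_length_error():
    with pytest.raises(ArchitectureError):
        net.conv_output_length(4, 7, 7, 0)


# ---------------------------------------------------------------------------
# Forward primitives vs oracles
# ---------------------------------------------------------------------------


def test_conv_bias_through_relu():
    x = np.zeros((10, 1))
    W = np.zeros((1, 1, 3))
    assert np.all(net.conv1d_relu(x, W, np.array([2.0])) == 2.0)
    assert np.all(net.conv1d_relu(x, W, np.array([-2.0])) == 0.0)


def test_conv_matches_loop_oracle():
    rng = np.random.default_rng(0)
    x = rng.standard_normal((30, 1))
    W = rng.standard_normal((1, 1, 3))
    b = rng.standard_normal(1)
    np.testing.assert_allclose(net.conv1d_relu(x, W, b), conv_loop(x, W, b), atol=1e-12)


def test_conv_multichannel_matches_loop():
    rng = np.random.default_rng(1)
    x = rng.standard_normal((20, 3))
    W = rng.standard_normal((4, 3, 5))
    b = rng.standard_normal(4)
    np.testing.assert_allclose(net.conv1d_relu(x, W, b), conv_loop(x, W, b), atol=1e-12)


def test_maxpool_examples():
    x = np.array([1.0, 9, 2, 3, 1, 0])[:, None]
    np.testing.assert_array_equal(net.maxpool(x, 3)[:, 0], [9.0, 3.0])
    const = np.full((10, 2), 5.0)
    out = net.maxpool(const, 3)
    assert out.shape == (3, 2) and np.all(out == 5.0)
    np.testing.assert_array_equal(net.maxpool(x, 1), x)
    with pytest.raises(ValueError):
        net.maxpool(x, 0)


def test_maxpool_matches_loop():
    rng = np.random.default_rng(2)
    x = rng.standard_normal((23, 4))
    np.testing.assert_allclose(net.maxpool(x, 7), pool_loop(x, 7), atol=0)


def test_lstm_zero_params_fixed_point():
    params = {f"lstm_{k}{g}": np.zeros((3, 3) if k in "WR" else 3) for k in "WR" for g in "fioc"}
    for g in "fioc":
        params[f"lstm_b{g}"] = np.zeros(3)
    P = np.random.default_rng(3).standard_normal((5, 3))
    np.testing.assert_allclose(net.lstm_forward(P, params), 0.0)


def test_lstm_scalar_hand_oracle():
    """J=Q=1, all W=1, R=0, b=0, input [1]: the hand-stepped recurrence."""
    params = {}
    for g in "fioc":
        params[f"lstm_W{g}"] = np.ones((1, 1))
        params[f"lstm_R{g}"] = np.zeros((1, 1))
        params[f"lstm_b{g}"] = np.zeros(1)
    h = net.lstm_forward(np.array([[1.0]]), params)
    s1 = sigmoid(1.0)
    c = s1 * np.tanh(1.0)
    expect = s1 * np.tanh(c)
    assert h[0] == pytest.approx(expect, abs=1e-12)


def test_lstm_matches_loop_oracle_and_bounds():
    rng = np.random.default_rng(4)
    q, j, T = 4, 3, 12
    params = {}
    for g in "fioc":
        params[f"lstm_W{g}"] = rng.standard_normal((q, j))
        params[f"lstm_R{g}"] = rng.standard_normal((q, q))
        params[f"lstm_b{g}"] = rng.standard_normal(q)
    P = rng.standard_normal((T, j))
    h = net.lstm_forward(P, params)
    np.testing.assert_allclose(h, lstm_loop(P, params), atol=1e-12)
    assert np.all(np.abs(h) < 1.0)


def test_full_forward_matches_composed_primitives():
    """The batched forward pass equals composing the standalone primitives
    (conv1d_relu, maxpool, lstm_forward, dense sigmoid) on a tiny model."""
    spec = net.NetSpec(((2, 3, 2), (2, 3, 2)), lstm_units=3, dense_layers=(1,))
    rng = np.random.default_rng(5)
    x = rng.standard_normal(50)
    params = net.init_params(spec, 50, seed=6)
    p, feats = net.forward(spec, params, x[None, :])
    a = x[:, None]
    for li, (_, _, K) in enumerate(spec.conv_blocks):
        a = net.conv1d_relu(a, params[f"conv{li}_W"], params[f"conv{li}_b"])
        a = net.maxpool(a, K)
    h = lstm_loop(a, params)
    np.testing.assert_allclose(feats[0], h, atol=1e-10)
    z = h @ params["dense0_W"] + params["dense0_b"]
    np.testing.assert_allclose(p[0], sigmoid(z)[0], atol=1e-10)


# ---------------------------------------------------------------------------
# Loss, weights, threshold
# ---------------------------------------------------------------------------


def test_weighted_bce_examples():
    y = np.array([1.0, 0.0])
    assert net.weighted_bce_loss(y, y, np.ones(2)) < 1e-5
    assert net.weighted_bce_loss([1.0], [0.5], [1.0]) == pytest.approx(np.log(2), abs=1e-9)
    rng = np.random.default_rng(7)
    yy = rng.integers(0, 2, 10).astype(float)
    pp_ = rng.uniform(0.1, 0.9, 10)
    eta = rng.uniform(0.5, 2.0, 10)
    assert net.weighted_bce_loss(yy, pp_, 2 * eta) == pytest.approx(
        2 * net.weighted_bce_loss(yy, pp_, eta)
    )
    with pytest.raises(ValueError):
        net.weighted_bce_loss([1.0], [0.5, 0.5], [1.0])


def test_class_weights_4_to_1():
    y = np.array([0] * 8 + [1] * 2)
    eta = net.class_weights(y)
    np.testing.assert_allclose(eta[:8], 0.625)
    np.testing.assert_allclose(eta[8:], 2.5)
    assert eta[:8].sum() == pytest.approx(eta[8:].sum())


def test_class_weights_balanced_and_property():
    np.testing.assert_allclose(net.class_weights(np.array([0, 1, 0, 1])), 1.0)
    rng = np.random.default_rng(8)
    for _ in range(20):
        y = rng.integers(0, 2, 30)
        if y.min() == y.max():
            continue
        eta = net.class_weights(y)
        assert eta[y == 1].sum() == pytest.approx(eta[y == 0].sum())
    with pytest.raises(ValueError):
        net.class_weights(np.ones(5))


def _bac(p, y, theta):
    pred = p >= theta
    return ((pred[y == 1].mean()) + ((~pred[y == 0]).mean())) / 2.0


def test_select_threshold_separated():
    p = np.array([0.1, 0.2, 0.8, 0.9])
    y = np.array([0, 0, 1, 1])
    theta = net.select_threshold(p, y)
    assert theta == pytest.approx(0.5)
    assert _bac(p, y, theta) == 1.0


def test_select_threshold_degenerate_tie():
    theta = net.select_threshold(np.full(6, 0.4), np.array([0, 1, 0, 1, 0, 1]))
    assert theta == 0.0  # smallest candidate; BAC 0.5 either way


@settings(derandomize=True, max_examples=30, deadline=None)
@given(seed=st.integers(0, 10_000))
def test_select_threshold_matches_exhaustive_grid(seed):
    rng = np.random.default_rng(seed)
    p = rng.uniform(0, 1, 20).round(3)
    y = rng.integers(0, 2, 20)
    if y.min() == y.max():
        y[0] = 1 - y[0]
    theta = net.select_threshold(p, y)
    grid = np.arange(0, 1.0001, 1e-4)
    best_grid = max(_bac(p, y, t) for t in grid)
    assert _bac(p, y, theta) == pytest.approx(best_grid, abs=1e-12)


def test_select_threshold_single_class():
    with pytest.raises(ThresholdError):
        net.select_threshold(np.array([0.2, 0.8]), np.array([1, 1]))


# ---------------------------------------------------------------------------
# Build / variants / inference
# ---------------------------------------------------------------------------


def test_build_network_sequence_lengths_and_determinism():
    m1 = net.build_network(net.proposed_spec(), 8, 250, seed=1)
    assert net.lstm_sequence_length(m1.spec, m1.input_len) == 40
    m2 = net.build_network(net.proposed_spec(), 2, 250, seed=1)
    assert net.lstm_sequence_length(m2.spec, m2.input_len) == 9
    m3 = net.build_network(net.proposed_spec(), 8, 250, seed=1)
    for k in m1.params:
        np.testing.assert_array_equal(m1.params[k], m3.params[k])


def test_build_network_too_short():
    with pytest.raises(ArchitectureError):
        net.build_network(net.proposed_spec(), 0.2, 250, seed=0)


def test_variant_specs():
    k = net.build_variant("kiranyaz")
    assert [b[0] for b in k.conv_blocks] == [32, 16]
    assert all(b[1] == 15 for b in k.conv_blocks)
    assert all(b[2] == 6 for b in k.conv_blocks)
    assert len(k.dense_layers) == 1 and k.lstm_units == 0
    z = net.build_variant("zubair")
    assert [b[0] for b in z.conv_blocks] == [32, 16, 8]
    a = net.build_variant("acharya")
    assert len(a.conv_blocks) == 4 and len(a.dense_layers) == 2
    assert [b[1] for b in a.conv_blocks] == [5, 5, 5, 4]
    with pytest.raises(ValueError):
        net.build_variant("lenet")
    for name in ("kiranyaz", "zubair", "acharya"):
        lengths = net.phase_lengths(net.build_variant(name), 1000)
        assert all(n >= 1 for n in lengths)


def test_predict_contract():
    from vfdetect.segmenter import Segment

    model = net.build_network(net.proposed_spec(), 2, 250, seed=2)
    model.theta = 0.5
    x = np.random.default_rng(9).standard_normal(500)
    seg = Segment(x, "Sh", "VF", "p0", "synthetic", 0.0)
    p1, d1 = net.predict(model, seg)
    p2, d2 = net.predict(model, seg)
    assert 0.0 <= p1 <= 1.0 and p1 == p2 and d1 == d2
    assert d1 in ("shock", "no_shock")
    with pytest.raises(ValueError):
        net.predict(model, Segment(x[:100], "Sh", "VF", "p0", "synthetic", 0.0))


def test_extract_lstm_features_contract():
    from vfdetect.segmenter import Segment

    model = net.build_network(net.proposed_spec(), 2, 250, seed=3)
    x = np.random.default_rng(10).standard_normal(500)
    feats = net.extract_lstm_features(model, Segment(x, "Sh", "VF", "p", "synthetic", 0.0))
    assert feats.shape == (20,)
    assert np.all(np.abs(feats) < 1.0)
    cnn_only = net.build_network(net.build_variant("zubair"), 2, 250, seed=3)
    with pytest.raises(FeatureError):
        net.extract_lstm_features(cnn_only, x)


def test_checkpoint_round_trip(tmp_path):
    model = net.build_network(net.proposed_spec(), 2, 250, seed=4)
    model.theta = 0.37
    net.save_checkpoint(model, tmp_path / "m.npz")
    back = net.load_checkpoint(tmp_path / "m.npz")
    assert back.spec == model.spec and back.theta == model.theta
    x = np.random.default_rng(11).standard_normal((3, 500))
    np.testing.assert_array_equal(model.predict_proba(x), back.predict_proba(x))


# ---------------------------------------------------------------------------
# Training behavior (scaled-down runs)
# ---------------------------------------------------------------------------


def test_training_reaches_high_bac_on_separable_cohort(separable_training):
    """On a cleanly separable 200-segment cohort the training-set balanced
    accuracy reaches 0.99 within 50 epochs."""
    segs, fitted, _ = separable_training
    p = fitted.predict_proba(segs.matrix())
    y = segs.labels()
    assert _bac(p, y, fitted.theta) >= 0.99


def test_training_loss_descends(separable_training):
    _, fitted, _ = separable_training
    assert fitted.train_log[-1] < fitted.train_log[0]


def test_training_deterministic():
    segs = make_separable_segments(n=60)
    cfg = net.TrainConfig(epochs=5, batch_size=16, seed=13)
    runs = []
    for _ in range(2):
        model = net.build_network(net.proposed_spec(), segs.L, segs.fs, seed=13)
        runs.append(net.train(model, segs, cfg))
    assert runs[0].train_log == runs[1].train_log
    assert runs[0].theta == runs[1].theta
    for k in runs[0].params:
        np.testing.assert_array_equal(runs[0].params[k], runs[1].params[k])
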