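"""PVNet building blocks (RoPE, EAA, ConvEncoder, SwiftFormer) and training."""

import numpy as np
import pytest

from sawoce import nn, pvnet, simulate
from sawoce.nn import Tensor
from sawoce.pvnet import (
    PVNet,
    PVNetConfig,
    TrainingConfig,
    eaa,
    eaa_macs,
    evaluate_mae,
    rope_rotate,
    train,
)


class TestRope:
    def test_zero_position_is_identity(self, rng):
        x = rng.standard_normal((5, 8))
        out = rope_rotate(x, np.zeros(5))
        assert np.allclose(out, x, atol=1e-15)

    def test_isometry(self, rng):
        x = rng.standard_normal((20, 16))
        m = rng.integers(0, 100, 20)
        out = rope_rotate(x, m)
        assert np.allclose(np.linalg.norm(out, axis=1), np.linalg.norm(x, axis=1),
                           atol=1e-12)

    def test_relative_shift_invariance(self, rng):
        """dot(rope(q,m), rope(k,n)) depends only on m - n."""
        for D in (8, 16, 48, 64):
            q = rng.standard_normal(D)
            k = rng.standard_normal(D)
            m, n, s = 7, 3, 11
            d1 = rope_rotate(q[None], [m])[0] @ rope_rotate(k[None], [n])[0]
            d2 = rope_rotate(q[None], [m + s])[0] @ rope_rotate(k[None], [n + s])[0]
            assert d1 == pytest.approx(d2, abs=1e-9)

    def test_odd_dimension_rejected(self, rng):
        with pytest.raises(ValueError, match="even"):
            rope_rotate(rng.standard_normal((3, 7)), np.arange(3))


def _eaa_loop_oracle(Q, K, w_a, W, b):
    """Index-by-index EAA implementation that also counts its multiplies."""
    N, D = Q.shape
    macs = 0
    s = np.empty(N)
    for i in range(N):
        acc = 0.0
        for d in range(D):
            acc += Q[i, d] * w_a[d]
            macs += 1
        s[i] = acc / np.sqrt(D)
    e = np.exp(s - s.max())
    alpha = e / e.sum()
    q = np.zeros(D)
    for i in range(N):
        for d in range(D):
            q[d] += alpha[i] * Q[i, d]
            macs += 1
    out = np.empty((N, D))
    for i in range(N):
        mod = np.empty(D)
        for d in range(D):
            mod[d] = K[i, d] * q[d]
            macs += 1
        out[i] = mod @ W + b + Q[i]
    return out, macs


class TestEAA:
    def test_singleton_token_identity(self, rng):
        Q = rng.standard_normal((1, 6))
        K = rng.standard_normal((1, 6))
        w_a = rng.standard_normal(6)
        out = eaa(Q, K, w_a)
        # alpha = 1 exactly, q = Q1, output = K*Q1 + Q1
        assert np.allclose(out, K * Q[0] + Q, atol=1e-15)

    def test_alpha_normalization(self, rng):
        Q = rng.standard_normal((9, 4))
        w_a = rng.standard_normal(4)
        s = Q @ w_a / 2.0
        alpha = np.exp(s - s.max())
        alpha /= alpha.sum()
        assert alpha.sum() == pytest.approx(1.0, abs=1e-12)

    def test_matches_loop_oracle(self, rng):
        Q = rng.standard_normal((7, 6))
        K = rng.standard_normal((7, 6))
        w_a = rng.standard_normal(6)
        W = rng.standard_normal((6, 6))
        b = rng.standard_normal(6)
        expected, _ = _eaa_loop_oracle(Q, K, w_a, W, b)
        assert np.allclose(eaa(Q, K, w_a, W, b), expected, atol=1e-9)

    def test_cost_linear_in_tokens(self, rng):
        """The attention core's multiply count doubles with the token count."""
        D = 6
        W = rng.standard_normal((D, D))
        b = rng.standard_normal(D)
        counts = {}
        for N in (8, 16, 32):
            Q = rng.standard_normal((N, D))
            _, macs = _eaa_loop_oracle(Q, Q, rng.standard_normal(D), W, b)
            counts[N] = macs
            assert macs == eaa_macs(N, D)
        assert counts[16] == 2 * counts[8]
        assert counts[32] == 2 * counts[16]

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            eaa(rng.standard_normal((3, 4)), rng.standard_normal((4, 4)),
                rng.standard_normal(4))

    def test_layer_agrees_with_reference_math(self, rng):
        """The autodiff EAA layer equals the plain-numpy formula on its own weights."""
        nn.set_default_dtype(np.float64)
        try:
            layer = pvnet.EAAttention(8, 10000.0, np.random.default_rng(0))
            x = rng.standard_normal((1, 5, 8))
            with nn.no_grad():
                out = layer(Tensor(x)).data[0]
            pos = np.arange(5)
            Q = rope_rotate(x[0] @ layer.wq.w.data + layer.wq.b.data, pos)
            K = rope_rotate(x[0] @ layer.wk.w.data + layer.wk.b.data, pos)
            expected = eaa(Q, K, layer.w_a.data, layer.proj.w.data, layer.proj.b.data)
            assert np.allclose(out, expected, atol=1e-9)
        finally:
            nn.set_default_dtype(np.float32)


class TestBlocks:
    def test_conv_encoder_zero_projection_is_identity(self, rng):
        block = pvnet.ConvEncoder(8, 2, np.random.default_rng(0))
        block.pw2.w.data[:] = 0
        block.pw2.b.data[:] = 0
        x = rng.standard_normal((2, 8, 6, 6)).astype(np.float32)
        with nn.no_grad():
            out = block(Tensor(x)).data
        assert np.allclose(out, x, atol=1e-12)

    def test_conv_encoder_preserves_shape_and_grads_flow(self, rng):
        block = pvnet.ConvEncoder(8, 2, np.random.default_rng(1))
        x = Tensor(rng.standard_normal((2, 8, 16, 16)))
        out = block(x)
        assert out.shape == x.shape
        nn.mean(nn.mul(out, out)).backward()
        for p in block.parameters():
            assert p.grad is not None and np.any(p.grad != 0)

    def test_swiftformer_preserves_shape_and_is_position_sensitive(self, rng):
        block = pvnet.SwiftFormerBlock(8, 10000.0, np.random.default_rng(2))
        x = rng.standard_normal((1, 8, 4, 4))
        with nn.no_grad():
            out = block(Tensor(x)).data
            # roll the spatial layout: same multiset of features, new positions
            x_rolled = np.roll(x, shift=2, axis=3)
            out_rolled = block(Tensor(x_rolled)).data
        assert out.shape == x.shape
        assert not np.allclose(out_rolled, np.roll(out, shift=2, axis=3), atol=1e-4)

    def test_channel_mismatch_rejected(self, rng):
        block = pvnet.ConvEncoder(8, 2, np.random.default_rng(3))
        with pytest.raises(ValueError, match="channel|depthwise"):
            with nn.no_grad():
                block(Tensor(rng.standard_normal((1, 4, 6, 6))))


@pytest.fixture(scope="module")
def tiny():
    return PVNet(PVNetConfig.preset("tiny"), seed=0)


class TestForward:
    def test_zero_image_gives_finite_scalar(self, tiny):
        tiny.eval()
        with nn.no_grad():
            out = tiny(Tensor(np.zeros((1, 1, 64, 64)))).data
        assert out.shape == (1,) and np.isfinite(out).all()

    def test_eval_mode_deterministic(self, tiny, rng):
        x = rng.standard_normal((2, 1, 64, 64))
        tiny.eval()
        with nn.no_grad():
            a = tiny(Tensor(x)).data
            b = tiny(Tensor(x)).data
        assert np.array_equal(a, b)

    def test_wrong_input_size_rejected(self, tiny, rng):
        with pytest.raises(ValueError, match="expected input"):
            with nn.no_grad():
                tiny(Tensor(rng.standard_normal((1, 1, 32, 32))))

    def test_parameter_count_matches_analytic_total(self, tiny):
        def conv_enc(d, r):
            return (9 * d + d) + 2 * d + (d * r * d + r * d) + (r * d * d + d)

        def swift(d):
            dw = 9 * d + d
            pw = d * d + d
            attn = 3 * (d * d + d) + d          # wq, wk, proj + w_a
            return dw + pw + attn + dw + 2 * d + pw

        dims, r = (16, 32, 48, 64), 2
        expected = (16 * 1 * 16 + 16) + 2 * 16              # stem conv + bn
        for i, d in enumerate(dims):
            expected += conv_enc(d, r) + swift(d)
            if i < 3:
                expected += 9 * d * dims[i + 1] + dims[i + 1] + 2 * dims[i + 1]
        expected += (64 * 32 + 32) + (32 * 1 + 1)           # head
        actual = sum(p.data.size for p in tiny.parameters())
        assert actual == expected

    def test_tiny_forward_under_one_second(self, tiny, rng):
        import time

        x = Tensor(rng.standard_normal((1, 1, 64, 64)))
        tiny.eval()
        with nn.no_grad():
            tiny(x)  # warm-up
            t0 = time.perf_counter()
            tiny(x)
            dt = time.perf_counter() - t0
        assert dt < 1.0


class TestTraining:
    def test_separable_velocities_learned_quickly(self):
        """Two well-separated classes (3 vs 6 m/s): val MAE < 0.5 within 30 epochs."""
        configs = [simulate.small_config(layers=((64, c),), noise_sigma=0.05,
                                         seed=int(50 + i))
                   for i, c in enumerate([3.0, 6.0, 3.0, 6.0])]
        X, y = simulate.make_training_set(configs, depths_per_volume=50, shuffle_seed=1)
        tcfg = TrainingConfig(lr=1e-3, batch_size=32, max_epochs=30, patience=15,
                              seed=0, target_val_mae=0.4)
        model, hist = train(X, y, tcfg, PVNetConfig.preset("tiny"))
        assert min(hist["val_mae"]) < 0.5
        assert len(hist["val_mae"]) <= 30

    def test_frozen_weights_patience_one_stops_after_two_epochs(self):
        X = np.zeros((40, 32, 32))
        y = np.full(40, 4.0)
        tcfg = TrainingConfig(lr=0.0, batch_size=16, max_epochs=10, patience=1, seed=0)
        _, hist = train(X, y, tcfg, PVNetConfig.preset("tiny"))
        assert len(hist["val_loss"]) == 2

    def test_same_seed_identical_history(self, rng):
        X = rng.standard_normal((60, 32, 32))
        y = rng.uniform(2, 8, 60)
        tcfg = TrainingConfig(lr=1e-3, batch_size=32, max_epochs=3, patience=2, seed=7)
        _, h1 = train(X, y, tcfg, PVNetConfig.preset("tiny"))
        _, h2 = train(X, y, tcfg, PVNetConfig.preset("tiny"))
        assert h1 == h2

    def test_empty_split_rejected(self):
        with pytest.raises(ValueError):
            train(np.zeros((2, 8, 8)), np.array([3.0, 4.0]),
                  TrainingConfig(val_frac=0.01), PVNetConfig.preset("tiny"))


class TestEvaluateMAE:
    class _Stub:
        def __init__(self, preds):
            self._p = np.asarray(preds, dtype=float)

        def predict(self, images):
            return self._p[: len(images)]

    def test_perfect_predictor(self):
        m = self._Stub([3.0, 4.0])
        assert evaluate_mae(m, np.zeros((2, 4, 4)), [3.0, 4.0]) == (0.0, 0.0)

    def test_constant_predictor_closed_form(self):
        m = self._Stub([5.0, 5.0])
        mean, std = evaluate_mae(m, np.zeros((2, 4, 4)), [4.0, 6.0])
        assert (mean, std) == (1.0, 0.0)

    def test_matches_per_pair_loop(self, rng):
        preds = rng.uniform(2, 8, 20)
        labels = rng.uniform(2, 8, 20)
        mean, std = evaluate_mae(self._Stub(preds), np.zeros((20, 4, 4)), labels)
        errs = [abs(p - t) for p, t in zip(preds, labels)]
        assert mean == pytest.approx(np.mean(errs), rel=1e-12)
        assert std == pytest.approx(np.std(errs), rel=1e-12)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            evaluate_mae(self._Stub([]), np.zeros((0, 4, 4)), [])
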