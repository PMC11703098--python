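"""Numerics of the neural-network building blocks: forward passes against
independent oracles, and analytic gradients against finite differences."""

import numpy as np
import pytest
from scipy import signal

from ajprofiler import _nn


def _finite_diff_check(layer, x, params, loss=lambda out: (out**2).sum() / 2, eps=1e-6, tol=1e-6):
    """Central-difference check of d(loss)/d(param) and d(loss)/d(input)."""
    out = layer.forward(x)
    for p in params:
        p.grad[...] = 0
    dx = layer.backward(out)  # dloss/dout = out for the quadratic loss
    for p in params:
        flat = p.value.ravel()
        rng = np.random.default_rng(0)
        for i in rng.integers(0, flat.size, size=min(5, flat.size)):
            orig = flat[i]
            flat[i] = orig + eps
            lp = loss(layer.forward(x))
            flat[i] = orig - eps
            lm = loss(layer.forward(x))
            flat[i] = orig
            num = (lp - lm) / (2 * eps)
            ana = p.grad.ravel()[i]
            assert num == pytest.approx(ana, rel=1e-4, abs=tol)
    # input gradient at a few positions
    flat = x.ravel()
    rng = np.random.default_rng(1)
    for i in rng.integers(0, flat.size, size=5):
        orig = flat[i]
        flat[i] = orig + eps
        lp = loss(layer.forward(x))
        flat[i] = orig - eps
        lm = loss(layer.forward(x))
        flat[i] = orig
        num = (lp - lm) / (2 * eps)
        assert num == pytest.approx(dx.ravel()[i], rel=1e-4, abs=tol)


class TestConv2D:
    def test_forward_matches_scipy_correlate(self):
        rng = np.random.default_rng(0)
        conv = _nn.Conv2D(cin=2, cout=3, k=3, stride=1, rng=rng, dtype=np.float64)
        x = np.random.default_rng(1).random((1, 8, 8, 2))
        out = conv.forward(x)
        W = conv.W.value.reshape(3, 2, 3, 3)  # (cout, cin, kh, kw)
        for co in range(3):
            expected = conv.b.value[co]
            for ci in range(2):
                expected = expected + signal.correlate2d(x[0, :, :, ci], W[co, ci], mode="same")
            np.testing.assert_allclose(out[0, :, :, co], expected, rtol=1e-10)

    def test_strided_output_size(self):
        conv = _nn.Conv2D(1, 4, k=3, stride=2, rng=np.random.default_rng(0))
        out = conv.forward(np.zeros((2, 64, 64, 1), np.float32))
        assert out.shape == (2, 32, 32, 4)

    @pytest.mark.parametrize("stride", [1, 2])
    def test_gradients(self, stride):
        rng = np.random.default_rng(2)
        conv = _nn.Conv2D(2, 3, k=3, stride=stride, rng=rng, dtype=np.float64)
        x = np.random.default_rng(3).random((2, 6, 6, 2))
        _finite_diff_check(conv, x, conv.params())


class TestDepthwiseConv2D:
    def test_forward_matches_per_channel_correlate(self):
        rng = np.random.default_rng(0)
        dw = _nn.DepthwiseConv2D(3, rng, dtype=np.float64)
        x = np.random.default_rng(1).random((1, 7, 7, 3))
        out = dw.forward(x)
        for c in range(3):
            expected = signal.correlate2d(x[0, :, :, c], dw.W.value[c], mode="same")
            np.testing.assert_allclose(out[0, :, :, c], expected, rtol=1e-10)

    def test_gradients(self):
        rng = np.random.default_rng(2)
        dw = _nn.DepthwiseConv2D(2, rng, dtype=np.float64)
        x = np.random.default_rng(3).random((2, 5, 5, 2))
        _finite_diff_check(dw, x, dw.params())


class TestPoolingAndNorm:
    def test_maxpool_matches_loop_oracle(self):
        pool = _nn.MaxPool2()
        x = np.random.default_rng(0).random((2, 8, 8, 3))
        out = pool.forward(x)
        for b in range(2):
            for i in range(4):
                for j in range(4):
                    for c in range(3):
                        assert out[b, i, j, c] == x[b, 2 * i : 2 * i + 2, 2 * j : 2 * j + 2, c].max()

    def test_maxpool_gradient_routes_to_argmax(self):
        pool = _nn.MaxPool2()
        x = np.random.default_rng(1).random((1, 4, 4, 1))
        out = pool.forward(x)
        dx = pool.backward(np.ones_like(out))
        assert dx.sum() == 4  # one unit per pooled window
        assert np.all((dx > 0) == (x == np.repeat(np.repeat(out, 2, 1), 2, 2)))

    def test_gap_is_channelwise_spatial_mean(self):
        gap = _nn.GlobalAvgPool()
        x = np.random.default_rng(2).random((3, 5, 5, 4))
        out = gap.forward(x)
        for b in range(3):
            for c in range(4):
                assert out[b, c] == pytest.approx(x[b, :, :, c].mean())

    def test_batchnorm_normalizes_in_train_mode(self):
        bn = _nn.BatchNorm(3, dtype=np.float64)
        x = np.random.default_rng(3).random((4, 6, 6, 3)) * 5 + 2
        out = bn.forward(x, train=True)
        np.testing.assert_allclose(out.mean(axis=(0, 1, 2)), 0, atol=1e-10)
        np.testing.assert_allclose(out.var(axis=(0, 1, 2)), 1, atol=1e-4)

    def test_batchnorm_gradients(self):
        bn = _nn.BatchNorm(2, dtype=np.float64)
        x = np.random.default_rng(4).random((3, 4, 4, 2))

        class _Wrap:
            def forward(self, x):
                return bn.forward(x, train=True)

            def backward(self, d):
                return bn.backward(d)

        _finite_diff_check(_Wrap(), x, bn.params())


class TestLossAndOptimizer:
    def test_cross_entropy_matches_logsumexp_oracle(self):
        from scipy.special import logsumexp

        logits = np.random.default_rng(0).random((6, 5)) * 3
        y = np.array([0, 1, 2, 3, 4, 0])
        loss, _ = _nn.softmax_cross_entropy(logits, y)
        expected = np.mean(logsumexp(logits, axis=1) - logits[np.arange(6), y])
        assert loss == pytest.approx(expected, rel=1e-6)

    def test_cross_entropy_gradient(self):
        logits = np.random.default_rng(1).random((4, 5)).astype(np.float64)
        y = np.array([1, 2, 0, 4])
        _, d = _nn.softmax_cross_entropy(logits, y)
        eps = 1e-7
        for i in [0, 7, 13]:
            orig = logits.ravel()[i]
            logits.ravel()[i] = orig + eps
            lp, _ = _nn.softmax_cross_entropy(logits, y)
            logits.ravel()[i] = orig - eps
            lm, _ = _nn.softmax_cross_entropy(logits, y)
            logits.ravel()[i] = orig
            assert (lp - lm) / (2 * eps) == pytest.approx(d.ravel()[i], rel=1e-4, abs=1e-8)

    def test_adam_reduces_quadratic(self):
        p = _nn.Param(np.array([5.0, -3.0]))
        opt = _nn.Adam([p], lr=0.1)
        for _ in range(200):
            opt.zero_grad()
            p.grad += p.value  # gradient of ||x||^2/2
            opt.step()
        assert np.linalg.norm(p.value) < 0.5
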