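"""Minimal numpy neural-network framework for the junction-morphology CNN.

Implements exactly the pieces the reduced-Xception classifier needs: plain
and depthwise-separable 2D convolutions (NHWC, im2col + BLAS), 2x2 max
pooling, ReLU, global average pooling, a dense classifier head, softmax
cross-entropy and Adam.  Forward passes cache what backward needs; backward
returns the input gradient so layers chain explicitly.

Weights default to float32; float64 is supported for finite-difference
gradient checking.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)


def _same_pad(size: int, k: int, s: int) -> tuple[int, int, int]:
    out = -(-size // s)  # ceil
    total = max((out - 1) * s + k - size, 0)
    return out, total // 2, total - total // 2


class Conv2D:
    """Plain convolution, 'same' padding, arbitrary stride."""

    def __init__(self, cin: int, cout: int, k: int, stride: int, rng: np.random.Generator, dtype=np.float32):
        std = np.sqrt(2.0 / (k * k * cin))
        self.W = Param((rng.standard_normal((cout, cin * k * k)) * std).astype(dtype))
        self.b = Param(np.zeros(cout, dtype=dtype))
        self.k, self.stride, self.cin, self.cout = k, stride, cin, cout

    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, h, w, c = x.shape
        k, s = self.k, self.stride
        ho, pt, pb = _same_pad(h, k, s)
        wo, pl, pr = _same_pad(w, k, s)
        xp = np.pad(x, ((0, 0), (pt, pb), (pl, pr), (0, 0)))
        win = sliding_window_view(xp, (k, k), axis=(1, 2))[:, ::s, ::s]  # (b,ho,wo,c,k,k)
        cols = np.ascontiguousarray(win).reshape(b * ho * wo, c * k * k)
        out = cols @ self.W.value.T + self.b.value
        self._cache = (cols, x.shape, (pt, pl), (ho, wo))
        return out.reshape(b, ho, wo, self.cout)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        cols, xshape, (pt, pl), (ho, wo) = self._cache
        b, h, w, c = xshape
        k, s = self.k, self.stride
        dflat = dout.reshape(-1, self.cout)
        self.W.grad += dflat.T @ cols
        self.b.grad += dflat.sum(axis=0)
        dcols = (dflat @ self.W.value).reshape(b, ho, wo, c, k, k)
        hp = h + pt + (_same_pad(h, k, s)[2])
        wp = w + pl + (_same_pad(w, k, s)[2])
        dxp = np.zeros((b, hp, wp, c), dtype=dout.dtype)
        for i in range(k):
            for j in range(k):
                dxp[:, i : i + ho * s : s, j : j + wo * s : s, :] += dcols[:, :, :, :, i, j]
        return dxp[:, pt : pt + h, pl : pl + w, :]


class DepthwiseConv2D:
    """3x3 depthwise convolution, stride 1, 'same' padding."""

    def __init__(self, c: int, rng: np.random.Generator, k: int = 3, dtype=np.float32):
        std = np.sqrt(2.0 / (k * k))
        self.W = Param((rng.standard_normal((c, k, k)) * std).astype(dtype))
        self.k, self.c = k, c

    def params(self):
        return [self.W]

    def forward(self, x: np.ndarray) -> np.ndarray:
        k = self.k
        p = k // 2
        b, h, w, c = x.shape
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        out = np.zeros_like(x)
        for i in range(k):
            for j in range(k):
                out += xp[:, i : i + h, j : j + w, :] * self.W.value[:, i, j]
        self._cache = (xp, x.shape)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xp, xshape = self._cache
        b, h, w, c = xshape
        k = self.k
        p = k // 2
        dxp = np.zeros_like(xp)
        for i in range(k):
            for j in range(k):
                self.W.grad[:, i, j] += (xp[:, i : i + h, j : j + w, :] * dout).sum(axis=(0, 1, 2))
                dxp[:, i : i + h, j : j + w, :] += dout * self.W.value[:, i, j]
        return dxp[:, p : p + h, p : p + w, :]


class SeparableConv2D:
    """Depthwise 3x3 followed by pointwise 1x1 (Xception-style)."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator, dtype=np.float32):
        self.dw = DepthwiseConv2D(cin, rng, dtype=dtype)
        self.pw = Conv2D(cin, cout, k=1, stride=1, rng=rng, dtype=dtype)

    def params(self):
        return self.dw.params() + self.pw.params()

    def forward(self, x):
        return self.pw.forward(self.dw.forward(x))

    def backward(self, dout):
        return self.dw.backward(self.pw.backward(dout))


class BatchNorm:
    """Per-channel batch normalization over (batch, H, W) with running stats."""

    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-5, dtype=np.float32):
        self.gamma = Param(np.ones(c, dtype=dtype))
        self.beta = Param(np.zeros(c, dtype=dtype))
        self.running_mean = np.zeros(c, dtype=dtype)
        self.running_var = np.ones(c, dtype=dtype)
        self.momentum, self.eps = momentum, eps

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        axes = tuple(range(x.ndim - 1))
        if train:
            mu = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mu
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mu, var = self.running_mean, self.running_var
        std = np.sqrt(var + self.eps)
        xhat = (x - mu) / std
        self._cache = (xhat, std, x.ndim)
        return self.gamma.value * xhat + self.beta.value

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, std, ndim = self._cache
        axes = tuple(range(ndim - 1))
        n = dout.size // dout.shape[-1]
        self.gamma.grad += (dout * xhat).sum(axis=axes)
        self.beta.grad += dout.sum(axis=axes)
        dxhat = dout * self.gamma.value
        s1 = dxhat.sum(axis=axes)
        s2 = (dxhat * xhat).sum(axis=axes)
        return (dxhat - s1 / n - xhat * s2 / n) / std


class ReLU:
    def params(self):
        return []

    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, 0)

    def backward(self, dout):
        return np.where(self._mask, dout, 0)


class MaxPool2:
    """2x2 max pooling, stride 2 (inputs must have even spatial dims)."""

    def params(self):
        return []

    def forward(self, x):
        b, h, w, c = x.shape
        r = x.reshape(b, h // 2, 2, w // 2, 2, c).transpose(0, 1, 3, 2, 4, 5).reshape(b, h // 2, w // 2, 4, c)
        self._idx = r.argmax(axis=3)
        self._shape = x.shape
        return np.take_along_axis(r, self._idx[:, :, :, None, :], axis=3)[:, :, :, 0, :]

    def backward(self, dout):
        b, h, w, c = self._shape
        dr = np.zeros((b, h // 2, w // 2, 4, c), dtype=dout.dtype)
        np.put_along_axis(dr, self._idx[:, :, :, None, :], dout[:, :, :, None, :], axis=3)
        return dr.reshape(b, h // 2, w // 2, 2, 2, c).transpose(0, 1, 3, 2, 4, 5).reshape(b, h, w, c)


class GlobalAvgPool:
    def params(self):
        return []

    def forward(self, x):
        self._shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, dout):
        b, h, w, c = self._shape
        return np.broadcast_to(dout[:, None, None, :] / (h * w), self._shape).astype(dout.dtype)


class Dense:
    def __init__(self, cin: int, cout: int, rng: np.random.Generator, dtype=np.float32):
        std = np.sqrt(2.0 / cin)
        self.W = Param((rng.standard_normal((cin, cout)) * std).astype(dtype))
        self.b = Param(np.zeros(cout, dtype=dtype))

    def params(self):
        return [self.W, self.b]

    def forward(self, x):
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, dout):
        self.W.grad += self._x.T @ dout
        self.b.grad += dout.sum(axis=0)
        return dout @ self.W.value.T


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy loss and gradient w.r.t. logits. ``y`` is 0-based."""
    p = softmax(logits)
    n = len(y)
    loss = float(-np.log(np.maximum(p[np.arange(n), y], 1e-12)).mean())
    dlogits = p.copy()
    dlogits[np.arange(n), y] -= 1.0
    return loss, (dlogits / n).astype(logits.dtype)


class Adam:
    def __init__(self, params: list[Param], lr: float = 1e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0

    def step(self):
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * p.grad
            v *= self.b2
            v += (1 - self.b2) * p.grad**2
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
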