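"""Minimal 3D convolutional network primitives in NumPy.

Forward and backward passes are written against BLAS-backed matmuls via an
im2col layout, which keeps a compact regression network for 32^3 volumes
trainable on a single CPU in minutes. Determinism is exact: all state is
initialized from an explicit Generator and there is no threading-dependent
reduction order beyond BLAS itself.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Layer:
    params: list
    grads: list

    def forward(self, x, train=True):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dout):  # pragma: no cover - interface
        raise NotImplementedError


class Conv3d(Layer):
    """3D convolution, kernel k, stride s, symmetric zero padding p."""

    def __init__(self, c_in, c_out, k=3, stride=2, pad=1, rng=None):
        rng = rng or np.random.default_rng(0)
        fan_in = c_in * k**3
        self.w = rng.standard_normal((fan_in, c_out)) * np.sqrt(2.0 / fan_in)
        self.b = np.zeros(c_out)
        self.k, self.stride, self.pad = k, stride, pad
        self.c_in, self.c_out = c_in, c_out
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def _out_dim(self, d):
        return (d + 2 * self.pad - self.k) // self.stride + 1

    def forward(self, x, train=True):
        n, c, d, h, w = x.shape
        k, s, p = self.k, self.stride, self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p)))
        win = sliding_window_view(xp, (k, k, k), axis=(2, 3, 4))[:, :, ::s, ::s, ::s]
        # win: (n, c, do, ho, wo, k, k, k) -> cols (n, L, c*k^3)
        do, ho, wo = win.shape[2:5]
        cols = win.transpose(0, 2, 3, 4, 1, 5, 6, 7).reshape(n, do * ho * wo, c * k**3)
        out = cols @ self.w + self.b
        if train:
            self._cache = (cols, x.shape, (do, ho, wo))
        return out.reshape(n, do, ho, wo, self.c_out).transpose(0, 4, 1, 2, 3)

    def backward(self, dout):
        cols, x_shape, (do, ho, wo) = self._cache
        n, c, d, h, w = x_shape
        k, s, p = self.k, self.stride, self.pad
        dflat = dout.transpose(0, 2, 3, 4, 1).reshape(n, do * ho * wo, self.c_out)
        self.grads[0][...] = np.tensordot(cols, dflat, axes=([0, 1], [0, 1]))
        self.grads[1][...] = dflat.sum(axis=(0, 1))
        dcols = dflat @ self.w.T  # (n, L, c*k^3)
        dcols = dcols.reshape(n, do, ho, wo, c, k, k, k).transpose(0, 4, 1, 2, 3, 5, 6, 7)
        dxp = np.zeros((n, c, d + 2 * p, h + 2 * p, w + 2 * p))
        for kd in range(k):
            for kh in range(k):
                for kw in range(k):
                    dxp[
                        :, :,
                        kd : kd + s * do : s,
                        kh : kh + s * ho : s,
                        kw : kw + s * wo : s,
                    ] += dcols[:, :, :, :, :, kd, kh, kw]
        return dxp[:, :, p : p + d, p : p + h, p : p + w]


class ReLU(Layer):
    params: list = []
    grads: list = []

    def forward(self, x, train=True):
        if train:
            self._mask = x > 0
        return np.maximum(x, 0.0)

    def backward(self, dout):
        return dout * self._mask


class GlobalAvgPool(Layer):
    """(n, c, d, h, w) -> (n, c) spatial mean."""

    params: list = []
    grads: list = []

    def forward(self, x, train=True):
        if train:
            self._shape = x.shape
        return x.mean(axis=(2, 3, 4))

    def backward(self, dout):
        n, c, d, h, w = self._shape
        return np.broadcast_to(dout[:, :, None, None, None], self._shape) / (d * h * w)


class Dense(Layer):
    def __init__(self, n_in, n_out, rng=None):
        rng = rng or np.random.default_rng(0)
        self.w = rng.standard_normal((n_in, n_out)) * np.sqrt(2.0 / n_in)
        self.b = np.zeros(n_out)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def forward(self, x, train=True):
        if train:
            self._x = x
        return x @ self.w + self.b

    def backward(self, dout):
        self.grads[0][...] = self._x.T @ dout
        self.grads[1][...] = dout.sum(axis=0)
        return dout @ self.w.T


class Sigmoid(Layer):
    params: list = []
    grads: list = []

    def forward(self, x, train=True):
        out = 1.0 / (1.0 + np.exp(-x))
        if train:
            self._out = out
        return out

    def backward(self, dout):
        return dout * self._out * (1.0 - self._out)


class Sequential:
    def __init__(self, layers):
        self.layers = layers

    def forward(self, x, train=True):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dout):
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    @property
    def params(self):
        return [p for l in self.layers for p in l.params]

    @property
    def grads(self):
        return [g for l in self.layers for g in l.grads]

    def state(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params]

    def load_state(self, state) -> None:
        for p, s in zip(self.params, state, strict=True):
            p[...] = s


class Adam:
    def __init__(self, params, grads, lr=3e-3, betas=(0.9, 0.999), eps=1e-8):
        self.params, self.grads = params, grads
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self):
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for p, g, m, v in zip(self.params, self.grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def mae_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean absolute error and its gradient wrt pred."""
    diff = pred - target
    return float(np.abs(diff).mean()), np.sign(diff) / diff.size
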