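"""Minimal CPU neural-network engine (convolutions, backprop, Adam).

Implements exactly the layers the localization networks need: strided
2-D convolutions (im2col), ReLU, fully-connected layers, global average
pooling and coordinate channels, each with an analytic backward pass,
plus an Adam optimizer and a stable binary cross-entropy.  Arrays follow
the (N, C, H, W) layout.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Param", "Layer", "Conv2d", "ReLU", "Linear", "GlobalAvgPool",
    "CoordChannels", "Flatten", "Sequential", "Adam",
    "bce_with_logits", "sigmoid",
]


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)


class Layer:
    def params(self) -> list:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError


class Conv2d(Layer):
    """3x3/1x1 strided convolution with 'same' padding, He-initialized."""

    def __init__(self, c_in: int, c_out: int, k: int = 3, stride: int = 1,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        fan_in = c_in * k * k
        self.W = Param(rng.standard_normal((c_out, c_in, k, k)) * np.sqrt(2.0 / fan_in))
        self.b = Param(np.zeros(c_out))
        self.k, self.stride, self.pad = k, stride, k // 2
        self._cache = None

    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        k, s, p = self.k, self.stride, self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        oh = (h + 2 * p - k) // s + 1
        ow = (w + 2 * p - k) // s + 1
        win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]  # N,C,OH,OW,k,k
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n, oh * ow, c * k * k)
        wm = self.W.value.reshape(self.W.value.shape[0], -1)
        out = cols @ wm.T + self.b.value
        self._cache = (cols, x.shape, (oh, ow))
        return out.reshape(n, oh, ow, -1).transpose(0, 3, 1, 2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        cols, x_shape, (oh, ow) = self._cache
        n, c, h, w = x_shape
        k, s, p = self.k, self.stride, self.pad
        c_out = self.W.value.shape[0]
        dmat = dy.transpose(0, 2, 3, 1).reshape(n, oh * ow, c_out)
        wm = self.W.value.reshape(c_out, -1)
        self.W.grad += np.einsum("npo,npq->oq", dmat, cols).reshape(self.W.value.shape)
        self.b.grad += dmat.sum(axis=(0, 1))
        dcols = (dmat @ wm).reshape(n, oh, ow, c, k, k)
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p))
        for i in range(k):
            for j in range(k):
                dxp[:, :, i:i + s * oh:s, j:j + s * ow:s] += dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
        return dxp[:, :, p:p + h, p:p + w]


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class Linear(Layer):
    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.W = Param(rng.standard_normal((c_out, c_in)) * np.sqrt(1.0 / c_in))
        self.b = Param(np.zeros(c_out))

    def params(self):
        return [self.W, self.b]

    def forward(self, x):
        self._x = x
        return x @ self.W.value.T + self.b.value

    def backward(self, dy):
        self.W.grad += dy.T @ self._x
        self.b.grad += dy.sum(axis=0)
        return dy @ self.W.value


class GlobalAvgPool(Layer):
    """(N, C, H, W) -> (N, C)."""

    def forward(self, x):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dy):
        n, c, h, w = self._shape
        return np.broadcast_to(dy[:, :, None, None], self._shape) / (h * w)


class CoordChannels(Layer):
    """Append two channels holding the normalized x and y pixel coordinates.

    Absolute position is informative in standing sagittal radiographs
    (the sacrum sits low, the thoracic levels high), and small
    convolution stacks have limited receptive fields; explicit
    coordinate channels let local filters exploit position directly.
    """

    def forward(self, x):
        n, c, h, w = x.shape
        gx = np.broadcast_to(np.linspace(-1, 1, w)[None, :], (h, w))
        gy = np.broadcast_to(np.linspace(-1, 1, h)[:, None], (h, w))
        g = np.broadcast_to(np.stack([gx, gy])[None], (n, 2, h, w))
        self._c = c
        return np.concatenate([x, g], axis=1)

    def backward(self, dy):
        return dy[:, : self._c]


class Flatten(Layer):
    def forward(self, x):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def forward(self, x):
        for l in self.layers:
            x = l.forward(x)
        return x

    def backward(self, dy):
        for l in reversed(self.layers):
            dy = l.backward(dy)
        return dy


class Adam:
    """Adam optimizer with bias correction."""

    def __init__(self, params: list, lr: float, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            m[...] = b1 * m + (1 - b1) * p.grad
            v[...] = b2 * v + (1 - b2) * p.grad ** 2
            mh = m / (1 - b1 ** self.t)
            vh = v / (1 - b2 ** self.t)
            p.value -= self.lr * mh / (np.sqrt(vh) + self.eps)


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    e = np.exp(z[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def bce_with_logits(z: np.ndarray, t: np.ndarray):
    """Mean binary cross-entropy from logits; returns (loss, dloss/dz)."""
    z = np.asarray(z, float)
    t = np.asarray(t, float)
    loss = np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z)))
    dz = (sigmoid(z) - t) / z.size
    return float(loss.mean()), dz
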