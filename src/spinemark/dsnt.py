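"""Differentiable spatial-to-numerical transform (soft-argmax) head.

A localization network emits one raw heatmap per landmark.  Each map is
normalized to a spatial probability distribution (softmax over all
cells), and the landmark coordinate is the expectation of a normalized
[-1, 1] coordinate grid under that distribution.  Because the expectation
is linear in the probabilities, the whole head is differentiable and the
network can be trained by directly minimizing the Euclidean distance
between predicted and target coordinates.

Coordinate convention: cell ``i`` of an ``n``-cell axis sits at
``(2 i + 1 - n) / n``, so pixel centers lie strictly inside (-1, 1) and
``denormalize`` maps grid coordinates back to 0-based pixel indices
exactly.
"""

from __future__ import annotations

import warnings

import numpy as np

__all__ = [
    "normalize_heatmap",
    "grid_coordinate",
    "grid_coords",
    "dsnt_expect",
    "spatial_softmax",
    "expect_batch",
    "coord_loss",
    "coord_loss_grad",
    "dsnt_backward",
    "denormalize",
    "normalize_pixel",
]

_EPS = 1e-12


def grid_coordinate(index: int, n: int) -> float:
    """Normalized coordinate of 0-based cell ``index`` on an ``n``-cell axis."""
    if not 0 <= index < n:
        raise ValueError(f"index {index} out of range for axis of {n} cells")
    return (2.0 * index + 1.0 - n) / n


def grid_coords(n: int) -> np.ndarray:
    """Vector of the ``n`` normalized cell-center coordinates."""
    return (2.0 * np.arange(n) + 1.0 - n) / n


def normalize_heatmap(raw: np.ndarray) -> np.ndarray:
    """Spatial softmax: strictly positive map summing to 1."""
    raw = np.asarray(raw, dtype=float)
    if not np.isfinite(raw).all():
        raise ValueError("heatmap contains non-finite values")
    z = raw - raw.max()
    e = np.exp(z)
    return e / e.sum()


def spatial_softmax(logits: np.ndarray) -> np.ndarray:
    """Softmax over the trailing two (spatial) axes of ``(..., H, W)`` logits."""
    z = logits - logits.max(axis=(-2, -1), keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=(-2, -1), keepdims=True)


def dsnt_expect(channel: np.ndarray) -> tuple:
    """Expected (x, y) in [-1, 1] of one normalized heatmap channel.

    Raises if the channel is not normalized (sum deviating from 1 by
    more than 1e-4).
    """
    p = np.asarray(channel, dtype=float)
    if abs(p.sum() - 1.0) > 1e-4:
        raise ValueError(f"heatmap channel not normalized (sum={p.sum():.6f})")
    h, w = p.shape
    x = float(p.sum(axis=0) @ grid_coords(w))
    y = float(p.sum(axis=1) @ grid_coords(h))
    return (x, y)


def expect_batch(probs: np.ndarray) -> np.ndarray:
    """Expectation over ``(..., H, W)`` normalized maps; returns ``(..., 2)``."""
    h, w = probs.shape[-2:]
    x = probs.sum(axis=-2) @ grid_coords(w)
    y = probs.sum(axis=-1) @ grid_coords(h)
    return np.stack([x, y], axis=-1)


def coord_loss(pred: np.ndarray, target: np.ndarray, mask=None) -> float:
    """Mean Euclidean distance between predicted and target coordinates.

    ``pred``/``target`` have shape ``(..., 2)``; ``mask`` (same leading
    shape) marks the entries that carry supervision — absent vertebrae
    and the invalid S1 lower corners are masked out rather than given
    fabricated targets.  An all-masked batch yields 0 with a warning.
    """
    pred = np.asarray(pred, float)
    target = np.asarray(target, float)
    if pred.shape != target.shape:
        raise ValueError("pred/target shape mismatch")
    d = np.sqrt(((pred - target) ** 2).sum(axis=-1))
    if mask is None:
        return float(d.mean())
    m = np.asarray(mask, bool)
    if not m.any():
        warnings.warn("coord_loss: all entries masked; loss defined as 0")
        return 0.0
    return float(d[m].mean())


def coord_loss_grad(pred: np.ndarray, target: np.ndarray, mask=None) -> np.ndarray:
    """Gradient of :func:`coord_loss` with respect to ``pred``."""
    pred = np.asarray(pred, float)
    target = np.asarray(target, float)
    diff = pred - target
    r = np.sqrt((diff ** 2).sum(axis=-1, keepdims=True))
    if mask is None:
        n = int(np.prod(pred.shape[:-1]))
    else:
        m = np.asarray(mask, bool)
        n = int(m.sum())
        if n == 0:
            return np.zeros_like(pred)
        diff = diff * m[..., None]
    return diff / (r + _EPS) / max(n, 1)


def dsnt_backward(probs: np.ndarray, dpred: np.ndarray) -> np.ndarray:
    """Backpropagate through softmax + expectation.

    ``probs``: ``(..., H, W)`` normalized maps; ``dpred``: ``(..., 2)``
    gradient at the coordinates.  Returns the gradient with respect to
    the raw logits.  For cell (i, j), d coord/d logit follows the softmax
    Jacobian: ``p * (g - sum(p * g))`` with ``g = dx * X_j + dy * Y_i``.
    """
    h, w = probs.shape[-2:]
    # g(i, j) = dx * X_j + dy * Y_i
    g = (dpred[..., 0][..., None, None] * grid_coords(w)[None, :]
         + dpred[..., 1][..., None, None] * grid_coords(h)[:, None])
    inner = (probs * g).sum(axis=(-2, -1), keepdims=True)
    return probs * (g - inner)


def denormalize(point, size) -> np.ndarray:
    """Map [-1, 1] coordinates to 0-based pixel coordinates.

    ``size`` is (w, h); ``x_pix = (x_norm * w + w - 1) / 2`` (same for y),
    the exact inverse of :func:`grid_coordinate` at cell centers.
    """
    p = np.asarray(point, dtype=float)
    wh = np.asarray(size, dtype=float)
    return (p * wh + wh - 1.0) / 2.0


def normalize_pixel(point, size) -> np.ndarray:
    """Map 0-based pixel coordinates to [-1, 1] (inverse of denormalize)."""
    p = np.asarray(point, dtype=float)
    wh = np.asarray(size, dtype=float)
    return (2.0 * p + 1.0 - wh) / wh
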