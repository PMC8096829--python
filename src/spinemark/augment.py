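"""Coordinate-aware training-time augmentations.

Every operation transforms the image and its landmark coordinates with
the same mapping, so the landmark/pixel correspondence is preserved.
The random caudal crop emulates radiographs with reduced fields of view:
it removes the lower part of the image so that L5, L4 or L3 becomes the
most caudal fully visible vertebra, preventing the presence classifier
from learning "the lowest vertebra is always the sacrum".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates
from skimage.transform import AffineTransform, warp

from .annotations import AnnotatedImage, CornerSet, VertebraLevel

__all__ = [
    "AugmentConfig",
    "random_caudal_crop",
    "random_rotate_flip",
    "horizontal_flip",
    "rotate",
    "elastic_and_noise",
    "normalize_intensity",
]

log = logging.getLogger(__name__)

_CAUDAL_TARGETS = {VertebraLevel.L3, VertebraLevel.L4, VertebraLevel.L5}
# horizontal flip swaps anterior<->posterior within each endplate:
# UA<->UP, LA<->LP
_FLIP_ORDER = [1, 0, 3, 2]


@dataclass
class AugmentConfig:
    """Augmentation strengths; all operations are no-ops at zero settings."""

    rotation_range: float = 10.0      # degrees, sampled uniform in +-range
    flip_prob: float = 0.5
    elastic_alpha: float = 0.0        # displacement amplitude, px
    elastic_sigma: float = 8.0        # displacement smoothness, px
    noise_sd: float = 0.02            # additive Gaussian intensity noise
    caudal_crop_prob: float = 0.5
    min_visible: int = 3
    max_attempts: int = 50
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.min_visible < 1:
            raise ValueError("min_visible must be >= 1")
        for p in (self.flip_prob, self.caudal_crop_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")


def random_caudal_crop(img: AnnotatedImage, config: AugmentConfig,
                       rng: np.random.Generator) -> AnnotatedImage:
    """Randomly remove the lower part of the image (training only).

    A cut y-coordinate is rejection-sampled uniformly from the lower half
    of the image and accepted when (a) the most caudal fully visible
    vertebra becomes L5, L4 or L3, and (b) at least ``min_visible``
    vertebrae remain.  Vertebrae with any corner at or below the cut are
    dropped from the landmark map.  If no admissible cut is found within
    ``max_attempts`` tries the input is returned unchanged.
    """
    h = img.pixels.shape[0]
    if len(img.landmarks) < config.min_visible:
        return img
    for _ in range(config.max_attempts):
        y_cut = rng.uniform(h / 2.0, h)
        kept = {
            lvl: cs for lvl, cs in img.landmarks.items()
            if (cs.points[cs.valid_mask][:, 1] < y_cut).all()
        }
        if len(kept) < config.min_visible or not kept:
            continue
        if max(kept) not in _CAUDAL_TARGETS:
            continue
        rows = int(np.ceil(y_cut))
        return AnnotatedImage(
            img.pixels[:rows].copy(),
            {lvl: cs.copy() for lvl, cs in kept.items()},
            img.image_id,
        )
    log.debug("caudal crop: no admissible cut for %s; returning input", img.image_id)
    return img


def horizontal_flip(img: AnnotatedImage) -> AnnotatedImage:
    """Mirror left-right, swapping anterior/posterior corner roles."""
    w = img.pixels.shape[1]
    lmk = {}
    for lvl, cs in img.landmarks.items():
        pts = cs.points[_FLIP_ORDER].copy()
        pts[:, 0] = (w - 1) - pts[:, 0]
        lmk[lvl] = CornerSet(pts, cs.valid_mask[_FLIP_ORDER].copy())
    return AnnotatedImage(img.pixels[:, ::-1].copy(), lmk, img.image_id)


def rotate(img: AnnotatedImage, angle_deg: float) -> AnnotatedImage:
    """Rotate image and landmarks by ``angle_deg`` about the image center.

    Landmarks map as ``p' = R(theta) (p - c) + c`` with the standard
    rotation matrix in (x, y) image coordinates (y down).
    """
    h, w = img.pixels.shape
    c = np.array([(w - 1) / 2.0, (h - 1) / 2.0])
    theta = np.radians(angle_deg)
    tf = (AffineTransform(translation=-c)
          + AffineTransform(rotation=theta)
          + AffineTransform(translation=c))
    pixels = warp(img.pixels.astype(float), tf.inverse, order=1, mode="constant", cval=0.0)
    lmk = {}
    for lvl, cs in img.landmarks.items():
        lmk[lvl] = CornerSet(tf(cs.points), cs.valid_mask.copy())
    return AnnotatedImage(pixels, lmk, img.image_id)


def _in_canvas(img: AnnotatedImage) -> bool:
    h, w = img.pixels.shape
    for cs in img.landmarks.values():
        pts = cs.points[cs.valid_mask]
        if pts.size and ((pts[:, 0] < 0) | (pts[:, 0] > w - 1)
                         | (pts[:, 1] < 0) | (pts[:, 1] > h - 1)).any():
            return False
    return True


def random_rotate_flip(img: AnnotatedImage, config: AugmentConfig,
                       rng: np.random.Generator) -> AnnotatedImage:
    """Random rotation (uniform in +-rotation_range) and horizontal flip.

    Rotations that would push a landmark off the canvas are resampled
    (up to 10 tries) with the angle shrunk; the identity is the fallback.
    """
    out = img
    if config.rotation_range > 0:
        r = config.rotation_range
        for _ in range(10):
            angle = rng.uniform(-r, r)
            cand = rotate(img, angle)
            if _in_canvas(cand):
                out = cand
                break
            r *= 0.5
    if config.flip_prob > 0 and rng.random() < config.flip_prob:
        out = horizontal_flip(out)
    return out


def elastic_and_noise(img: AnnotatedImage, config: AugmentConfig,
                      rng: np.random.Generator) -> AnnotatedImage:
    """Smooth random displacement field plus additive Gaussian pixel noise.

    The displacement field (Gaussian-filtered white noise, std scaled to
    ``elastic_alpha`` px, smoothness ``elastic_sigma`` px) is applied to
    the pixels and evaluated at each landmark, so for smooth fields the
    landmark stays on the same anatomical point to sub-pixel accuracy.
    With ``elastic_alpha == 0`` the landmarks are untouched bit-for-bit.
    """
    h, w = img.pixels.shape
    pixels = img.pixels.astype(float)
    lmk = {lvl: cs.copy() for lvl, cs in img.landmarks.items()}

    if config.elastic_alpha > 0:
        fields = []
        for _ in range(2):
            f = gaussian_filter(rng.standard_normal((h, w)), config.elastic_sigma)
            sd = f.std()
            fields.append(f / sd * config.elastic_alpha if sd > 0 else np.zeros_like(f))
        dx, dy = fields
        yy, xx = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
        # out(p) = in(p - d(p)); a landmark q then moves to ~ q + d(q)
        pixels = map_coordinates(pixels, [yy - dy, xx - dx], order=1, mode="nearest")
        for lvl, cs in lmk.items():
            pts = cs.points.copy()
            for i in range(pts.shape[0]):
                if not cs.valid_mask[i]:
                    continue
                x, y = pts[i]
                ddx = map_coordinates(dx, [[y], [x]], order=1, mode="nearest")[0]
                ddy = map_coordinates(dy, [[y], [x]], order=1, mode="nearest")[0]
                pts[i] = (np.clip(x + ddx, 0, w - 1), np.clip(y + ddy, 0, h - 1))
            lmk[lvl] = CornerSet(pts, cs.valid_mask.copy())

    if config.noise_sd > 0:
        pixels = pixels + rng.normal(0.0, config.noise_sd, size=pixels.shape)
    return AnnotatedImage(np.clip(pixels, 0.0, 1.0), lmk, img.image_id)


def normalize_intensity(pixels: np.ndarray, mode: str = "depth") -> np.ndarray:
    """Scale intensities to [0, 1].

    ``depth`` divides integer images by their bit-depth maximum (float
    input is assumed already scaled and passed through); ``minmax``
    stretches to the full range and maps a constant image to zeros with
    a warning.
    """
    arr = np.asarray(pixels)
    if mode == "depth":
        if np.issubdtype(arr.dtype, np.integer):
            depth = 65535.0 if arr.dtype.itemsize > 1 else 255.0
            return arr.astype(float) / depth
        return np.clip(arr.astype(float), 0.0, 1.0)
    if mode == "minmax":
        arr = arr.astype(float)
        lo, hi = float(arr.min()), float(arr.max())
        if hi <= lo:
            import warnings

            warnings.warn("normalize_intensity: constant image mapped to zeros")
            return np.zeros_like(arr)
        return (arr - lo) / (hi - lo)
    raise ValueError(f"unknown mode {mode!r}")
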