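"""Deterministic coordinate arithmetic for the two-stage pipeline.

Covers the invertible crop/resize transforms used to move landmarks
between the original radiograph frame and the network input frames, the
extended bounding box used to cut single-vertebra crops, and the
endplate-line angle computations (L1-L5 / L1-S1 lordosis, sacral slope).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
from skimage.transform import resize as _sk_resize

from .annotations import CornerSet, VertebraLevel

__all__ = [
    "GeometryError",
    "BoundingBox",
    "CropTransform",
    "AngleReport",
    "extended_bbox",
    "crop_resize",
    "to_original",
    "endplate_angle",
    "sacral_slope",
    "angles_from_corners",
]


class GeometryError(ValueError):
    """Degenerate geometry (zero-extent box, coincident line points...)."""


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned box in original-image pixel coordinates."""

    x_min: float
    y_min: float
    x_max: float
    y_max: float

    def __post_init__(self) -> None:
        if not (self.x_min < self.x_max and self.y_min < self.y_max):
            raise GeometryError(f"degenerate bounding box {self}")

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min

    def clipped(self, image_size) -> "BoundingBox":
        """Clip to image bounds; ``image_size`` is (width, height)."""
        w, h = image_size
        return BoundingBox(
            max(0.0, self.x_min), max(0.0, self.y_min),
            min(float(w), self.x_max), min(float(h), self.y_max),
        )


@dataclass(frozen=True)
class CropTransform:
    """Invertible map between original-image and crop/resized pixels.

    Forward: ``p_out = (p_orig - offset) * scale``; inverse adds the
    crop origin back after undoing the resize, which is exactly the
    geometrical transformation chain used to report refined corners in
    the original reference frame.
    """

    offset: tuple
    scale: tuple
    output_size: tuple

    def forward(self, points: np.ndarray) -> np.ndarray:
        p = np.asarray(points, dtype=float)
        return (p - np.asarray(self.offset)) * np.asarray(self.scale)

    def inverse(self, points: np.ndarray) -> np.ndarray:
        p = np.asarray(points, dtype=float)
        return p / np.asarray(self.scale) + np.asarray(self.offset)


def to_original(points: np.ndarray, transform: CropTransform) -> np.ndarray:
    """Map points from a transform's output frame back to the original frame."""
    return transform.inverse(points)


def extended_bbox(corners, extension: float, image_size) -> BoundingBox:
    """Tight box around the valid corners, grown by ``extension`` per side length.

    The grown box adds ``extension/2 * span`` of margin on each side of
    each axis (e.g. extension 0.7 grows a span of 20 px to 34 px,
    centered), then clips to the image bounds.

    ``corners`` may be a :class:`CornerSet` or an (N, 2) point array.
    Raises :class:`GeometryError` when fewer than 2 valid corners exist
    or the points have zero extent along either axis.
    """
    if extension < 0:
        raise ValueError("extension must be >= 0")
    pts = corners.valid_points if isinstance(corners, CornerSet) else np.asarray(corners, float)
    pts = pts.reshape(-1, 2)
    if pts.shape[0] < 2:
        raise GeometryError("need at least 2 valid corners for a bounding box")
    x_min, y_min = pts.min(axis=0)
    x_max, y_max = pts.max(axis=0)
    span_x, span_y = x_max - x_min, y_max - y_min
    if span_x <= 0 or span_y <= 0:
        raise GeometryError("corner set has zero extent along one axis")
    mx, my = 0.5 * extension * span_x, 0.5 * extension * span_y
    return BoundingBox(x_min - mx, y_min - my, x_max + mx, y_max + my).clipped(image_size)


def crop_resize(image: np.ndarray, box: BoundingBox, output_size):
    """Crop ``box`` from ``image`` and resize to ``output_size`` (w, h).

    Uses cubic interpolation and does not preserve the aspect ratio or
    modify the dynamic range.  Returns ``(crop, CropTransform)`` where the
    transform maps original-frame points into the output frame.
    """
    out_w, out_h = int(output_size[0]), int(output_size[1])
    if out_w <= 0 or out_h <= 0:
        raise ValueError("output_size must be positive")
    h, w = image.shape
    x0 = int(np.floor(max(0.0, box.x_min)))
    y0 = int(np.floor(max(0.0, box.y_min)))
    x1 = int(np.ceil(min(float(w), box.x_max)))
    y1 = int(np.ceil(min(float(h), box.y_max)))
    if x1 <= x0 or y1 <= y0:
        raise GeometryError("box does not overlap image")
    crop = image[y0:y1, x0:x1]
    ch, cw = crop.shape
    if (cw, ch) == (out_w, out_h):
        out = crop.astype(float, copy=True)
    else:
        out = _sk_resize(crop.astype(float), (out_h, out_w), order=3,
                         mode="edge", anti_aliasing=False, preserve_range=True)
    tf = CropTransform(offset=(float(x0), float(y0)),
                       scale=(out_w / cw, out_h / ch),
                       output_size=(out_w, out_h))
    return out, tf


# ---------------------------------------------------------------------------
# Angles
# ---------------------------------------------------------------------------

def _line_direction(p0, p1) -> np.ndarray:
    d = np.asarray(p1, float) - np.asarray(p0, float)
    if np.hypot(*d) == 0:
        raise GeometryError("coincident points do not define a line")
    return d


def endplate_angle(line_a, line_b) -> float:
    """Unsigned acute angle in degrees between two endplate lines.

    Each argument is a pair of points.  Implemented with direction
    vectors (atan2 of |cross| over |dot|), so vertical endplates are
    handled without slope infinities.  Result lies in [0, 90].
    """
    u = _line_direction(*line_a)
    v = _line_direction(*line_b)
    cross = abs(u[0] * v[1] - u[1] * v[0])
    dot = abs(u[0] * v[0] + u[1] * v[1])
    return float(np.degrees(np.arctan2(cross, dot)))


def sacral_slope(s1_upper) -> float:
    """Angle of the S1 upper endplate to the horizontal, in [0, 90] degrees."""
    p0, p1 = np.asarray(s1_upper, float).reshape(2, 2)
    return endplate_angle((p0, p1), ((0.0, 0.0), (1.0, 0.0)))


@dataclass(frozen=True)
class AngleReport:
    """L1-L5 lordosis, L1-S1 lordosis and sacral slope, in degrees.

    Each angle is None when its landmarks are unavailable.  Angles are
    unsigned, in [0, 90].
    """

    l1_l5: Optional[float] = None
    l1_s1: Optional[float] = None
    ss: Optional[float] = None

    def as_dict(self) -> dict:
        return {"L1_L5": self.l1_l5, "L1_S1": self.l1_s1, "SS": self.ss}


def _endplate(landmarks: Mapping, level: VertebraLevel, which: str):
    cs = landmarks.get(level)
    if cs is None:
        return None
    idx = (0, 1) if which == "upper" else (2, 3)
    if not (cs.valid_mask[idx[0]] and cs.valid_mask[idx[1]]):
        return None
    pts = cs.points[list(idx)]
    if np.allclose(pts[0], pts[1]):
        return None
    return pts


def angles_from_corners(landmarks: Mapping) -> AngleReport:
    """Compute the three clinical angles from a landmark map.

    L1-L5 is the angle between the L1 upper and L5 lower endplate lines;
    L1-S1 between the L1 upper and S1 upper endplates; SS the angle of
    the S1 upper endplate to the horizontal.  Missing landmarks yield
    None for the affected angles.
    """
    l1u = _endplate(landmarks, VertebraLevel.L1, "upper")
    l5l = _endplate(landmarks, VertebraLevel.L5, "lower")
    s1u = _endplate(landmarks, VertebraLevel.S1, "upper")
    return AngleReport(
        l1_l5=endplate_angle(l1u, l5l) if l1u is not None and l5l is not None else None,
        l1_s1=endplate_angle(l1u, s1u) if l1u is not None and s1u is not None else None,
        ss=sacral_slope(s1u) if s1u is not None else None,
    )
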