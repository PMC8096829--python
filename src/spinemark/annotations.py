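"""Domain types and annotation I/O for vertebral corner landmarks.

The unit of data flowing through the pipeline is an :class:`AnnotatedImage`:
a grayscale sagittal radiograph plus, for each visible vertebral level
(C2 .. S1), the pixel coordinates of the four vertebral-body corners.

Conventions
-----------
* Pixel coordinates are 0-based, origin at the top-left, x rightward,
  y downward (standard raster convention).
* Corners are stored in the fixed order
  ``[upper-anterior, upper-posterior, lower-anterior, lower-posterior]``
  (``UA, UP, LA, LP``).  A fixed order is required so that the four
  heatmap channels of the localization networks mean the same corner on
  every image.
* S1 has only an upper endplate, so only its two upper corners are valid;
  the lower two slots exist but are masked out of every loss and metric.
"""

from __future__ import annotations

import csv
import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

__all__ = [
    "VertebraLevel",
    "CornerSet",
    "AnnotatedImage",
    "CORNER_NAMES",
    "N_LEVELS",
    "N_CORNERS",
    "AnnotationError",
    "AnnotationParseError",
    "DuplicateRecordError",
    "read_annotations",
    "write_annotations",
    "presence_from_landmarks",
    "read_image",
    "write_image",
]

N_LEVELS = 24
N_CORNERS = 4
CORNER_NAMES = ("UA", "UP", "LA", "LP")

_LEVEL_NAMES = (
    ["C%d" % i for i in range(2, 8)]
    + ["T%d" % i for i in range(1, 13)]
    + ["L%d" % i for i in range(1, 6)]
    + ["S1"]
)


class VertebraLevel(enum.IntEnum):
    """The 24 spine levels C2..S1, ordered cranial to caudal.

    The integer value is the ordinal (0 = C2 ... 23 = S1), so comparisons
    follow anatomical order and the value indexes the 24-way network
    outputs directly.
    """

    C2 = 0; C3 = 1; C4 = 2; C5 = 3; C6 = 4; C7 = 5
    T1 = 6; T2 = 7; T3 = 8; T4 = 9; T5 = 10; T6 = 11
    T7 = 12; T8 = 13; T9 = 14; T10 = 15; T11 = 16; T12 = 17
    L1 = 18; L2 = 19; L3 = 20; L4 = 21; L5 = 22; S1 = 23

    @property
    def ordinal(self) -> int:
        return int(self)

    @classmethod
    def from_name(cls, name: str) -> "VertebraLevel":
        try:
            return cls[name.strip()]
        except KeyError:
            raise KeyError(f"unknown vertebra level {name!r}") from None


assert [lvl.name for lvl in VertebraLevel] == _LEVEL_NAMES


class AnnotationError(Exception):
    """Base class for annotation-file errors."""


class AnnotationParseError(AnnotationError):
    """A malformed row; the message names the 1-based line number."""


class DuplicateRecordError(AnnotationError):
    """The same (image_id, level, corner) appeared twice."""


@dataclass
class CornerSet:
    """Four corner landmarks of one vertebral body.

    ``points`` is a (4, 2) float array of (x, y) pixel coordinates in the
    order UA, UP, LA, LP; ``valid_mask`` flags which slots hold real
    landmarks.  Invalid slots contain NaN.
    """

    points: np.ndarray
    valid_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(N_CORNERS, 2)
        if self.valid_mask is None:
            self.valid_mask = ~np.isnan(self.points).any(axis=1)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool).reshape(N_CORNERS)
        pts = self.points[self.valid_mask]
        if pts.size and (~np.isfinite(pts)).any():
            raise ValueError("valid corner coordinates must be finite")
        if pts.size and (pts < 0).any():
            raise ValueError("valid corner coordinates must be non-negative")

    @property
    def valid_points(self) -> np.ndarray:
        return self.points[self.valid_mask]

    def upper(self) -> np.ndarray:
        """The two upper-endplate points (UA, UP)."""
        return self.points[:2]

    def lower(self) -> np.ndarray:
        """The two lower-endplate points (LA, LP)."""
        return self.points[2:]

    def copy(self) -> "CornerSet":
        return CornerSet(self.points.copy(), self.valid_mask.copy())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CornerSet):
            return NotImplemented
        if not np.array_equal(self.valid_mask, other.valid_mask):
            return False
        m = self.valid_mask
        return np.allclose(self.points[m], other.points[m], atol=0.0)


@dataclass
class AnnotatedImage:
    """A grayscale image plus per-level corner landmarks.

    ``pixels`` is a 2-D float array (rows = y, columns = x) with
    intensities in [0, 1]; ``landmarks`` maps :class:`VertebraLevel` to
    :class:`CornerSet` in original-image pixel coordinates.
    """

    pixels: np.ndarray
    landmarks: dict
    image_id: str = ""

    @property
    def shape(self) -> tuple:
        return self.pixels.shape

    @property
    def size(self) -> tuple:
        """(width, height) in pixels."""
        h, w = self.pixels.shape
        return (w, h)

    def levels(self) -> list:
        return sorted(self.landmarks.keys())

    def copy(self) -> "AnnotatedImage":
        return AnnotatedImage(
            self.pixels.copy(),
            {lvl: cs.copy() for lvl, cs in self.landmarks.items()},
            self.image_id,
        )


def presence_from_landmarks(landmarks: Mapping) -> np.ndarray:
    """Derive the 24-element presence vector from a landmark map.

    A level counts as present when it has at least two valid corners
    (S1 legitimately has only its two upper-endplate corners).
    """
    flags = np.zeros(N_LEVELS, dtype=bool)
    for lvl, cs in landmarks.items():
        if int(np.sum(cs.valid_mask)) >= 2:
            flags[VertebraLevel(lvl).ordinal] = True
    return flags


# ---------------------------------------------------------------------------
# Annotation CSV dialect: header `image_id,level,corner,x,y`; one row per
# valid corner; coordinates printed with at most 3 decimals; UTF-8, LF.
# ---------------------------------------------------------------------------

_HEADER = ["image_id", "level", "corner", "x", "y"]


def _fmt(v: float) -> str:
    s = f"{v:.3f}".rstrip("0").rstrip(".")
    return s if s else "0"


def write_annotations(landmarks_by_image: Mapping[str, Mapping], path) -> None:
    """Write a landmark map to the annotation CSV format.

    Row order is deterministic: image_id, then level ordinal, then corner
    order UA, UP, LA, LP.  Only valid corners produce rows, so S1 yields
    two rows.  ``read_annotations`` inverts this exactly.
    """
    path = Path(path)
    lines = [",".join(_HEADER)]
    for image_id in sorted(landmarks_by_image):
        lmk = landmarks_by_image[image_id]
        for lvl in sorted(lmk, key=lambda l: VertebraLevel(l).ordinal):
            cs = lmk[lvl]
            for c in range(N_CORNERS):
                if not cs.valid_mask[c]:
                    continue
                x, y = cs.points[c]
                lines.append(
                    f"{image_id},{VertebraLevel(lvl).name},{CORNER_NAMES[c]},{_fmt(x)},{_fmt(y)}"
                )
    path.write_text("\n".join(lines) + "\n", encoding="utf-8", newline="\n")


def read_annotations(path) -> dict:
    """Read an annotation CSV into ``{image_id: {level: CornerSet}}``.

    Raises :class:`AnnotationParseError` for malformed rows (naming the
    line number) and :class:`DuplicateRecordError` for repeated
    (image_id, level, corner) records.  If S1 arrives with four annotated
    corners the lower two are accepted but down-masked, since only its
    upper endplate carries meaning downstream.
    """
    path = Path(path)
    out: dict = {}
    with path.open("r", encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise AnnotationParseError(f"{path}: empty file, expected header") from None
        if [h.strip() for h in header] != _HEADER:
            raise AnnotationParseError(f"{path}: line 1: bad header {header!r}")
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != 5:
                raise AnnotationParseError(f"{path}: line {lineno}: expected 5 fields, got {len(row)}")
            image_id, level_s, corner_s, x_s, y_s = (f.strip() for f in row)
            try:
                lvl = VertebraLevel.from_name(level_s)
            except KeyError:
                raise AnnotationParseError(f"{path}: line {lineno}: unknown level {level_s!r}") from None
            if corner_s not in CORNER_NAMES:
                raise AnnotationParseError(f"{path}: line {lineno}: unknown corner {corner_s!r}")
            try:
                x, y = float(x_s), float(y_s)
            except ValueError:
                raise AnnotationParseError(f"{path}: line {lineno}: non-numeric coordinate") from None
            c = CORNER_NAMES.index(corner_s)
            img = out.setdefault(image_id, {})
            if lvl in img and not np.isnan(img[lvl][c, 0]):
                raise DuplicateRecordError(
                    f"{path}: line {lineno}: duplicate record ({image_id}, {level_s}, {corner_s})"
                )
            img.setdefault(lvl, np.full((N_CORNERS, 2), np.nan))[c] = (x, y)
    result: dict = {}
    for image_id, lvls in out.items():
        result[image_id] = {}
        for lvl, pts in lvls.items():
            mask = ~np.isnan(pts).any(axis=1)
            if lvl == VertebraLevel.S1:
                mask = mask & np.array([True, True, False, False])
            result[image_id][lvl] = CornerSet(pts, mask)
    return result


# ---------------------------------------------------------------------------
# Image readers/writers
# ---------------------------------------------------------------------------

def read_image(path) -> np.ndarray:
    """Read a grayscale image as a float array in [0, 1].

    PNG/JPEG are scaled by their bit depth (8- or 16-bit); single-frame
    DICOM files (.dcm) have their pixel array min-max rescaled to [0, 1].
    """
    path = Path(path)
    if path.suffix.lower() in (".dcm", ".dicom"):
        import pydicom

        ds = pydicom.dcmread(str(path))
        arr = ds.pixel_array.astype(float)
        if arr.ndim != 2:
            raise ValueError(f"{path}: expected a single-frame grayscale DICOM")
        lo, hi = float(arr.min()), float(arr.max())
        return (arr - lo) / (hi - lo) if hi > lo else np.zeros_like(arr)
    import imageio.v3 as iio

    raw = iio.imread(str(path))
    arr = raw[..., :3].mean(axis=-1) if raw.ndim == 3 else raw.astype(float)
    if np.issubdtype(raw.dtype, np.integer):
        depth = 65535.0 if raw.dtype.itemsize > 1 else 255.0
        arr = arr / depth
    return np.clip(arr.astype(float), 0.0, 1.0)


def write_image(pixels: np.ndarray, path) -> None:
    """Write a [0, 1] float image as 8-bit grayscale PNG."""
    import imageio.v3 as iio

    arr = np.clip(np.asarray(pixels, dtype=float), 0.0, 1.0)
    iio.imwrite(str(path), (arr * 255.0 + 0.5).astype(np.uint8))
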