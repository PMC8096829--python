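import math

import numpy as np
import pytest

from spinemark.annotations import CornerSet, VertebraLevel
from spinemark.geometry import (
    BoundingBox,
    GeometryError,
    angles_from_corners,
    crop_resize,
    endplate_angle,
    extended_bbox,
    sacral_slope,
    to_original,
)


def _rect_corners(x0, y0, w, h):
    return np.array([[x0 + w, y0], [x0, y0], [x0 + w, y0 + h], [x0, y0 + h]])


class TestExtendedBbox:
    def test_zero_extension_is_tight_box(self):
        b = extended_bbox(_rect_corners(10, 20, 20, 40), 0.0, (1000, 1000))
        assert (b.x_min, b.y_min, b.x_max, b.y_max) == (10, 20, 30, 60)

    def test_seventy_percent_growth_centered(self):
        b = extended_bbox(_rect_corners(10, 20, 20, 40), 0.7, (1000, 1000))
        assert (b.x_min, b.y_min, b.x_max, b.y_max) == (3, 6, 37, 74)
        assert b.width == pytest.approx(20 * 1.7)
        assert b.height == pytest.approx(40 * 1.7)

    def test_clipped_at_border_and_still_valid(self):
        b = extended_bbox(_rect_corners(1, 2, 20, 40), 0.7, (100, 50))
        assert b.x_min == 0 and b.y_min == 0
        assert b.x_max <= 100 and b.y_max <= 50
        assert b.width > 0 and b.height > 0

    def test_degenerate_extent_raises(self):
        pts = np.array([[10, 20], [30, 20]])  # zero y extent
        with pytest.raises(GeometryError):
            extended_bbox(pts, 0.7, (100, 100))
        with pytest.raises(GeometryError):
            extended_bbox(np.array([[10, 20]]), 0.7, (100, 100))


class TestCropResize:
    def test_identity_size_has_unit_scale(self, rng):
        img = rng.random((50, 60))
        box = BoundingBox(10, 5, 30, 45)
        crop, tf = crop_resize(img, box, (20, 40))
        assert crop.shape == (40, 20)
        assert tf.scale == (1.0, 1.0)
        assert np.allclose(crop, img[5:45, 10:30])

    def test_aspect_ratio_not_preserved(self, rng):
        img = rng.random((200, 200))
        crop, tf = crop_resize(img, BoundingBox(0, 0, 100, 50), (512, 512))
        assert crop.shape == (512, 512)
        assert tf.scale == (5.12, 10.24)

    def test_forward_inverse_round_trip(self, rng):
        img = rng.random((128, 128))
        for _ in range(50):
            x0, y0 = rng.uniform(0, 60, 2)
            w, h = rng.uniform(10, 60, 2)
            box = BoundingBox(x0, y0, x0 + w, y0 + h)
            _, tf = crop_resize(img, box, (64, 48))
            pts = rng.uniform(0, 120, (20, 2))
            back = to_original(tf.forward(pts), tf)
            assert np.abs(back - pts).max() < 1e-6

    def test_bad_output_size_rejected(self, rng):
        with pytest.raises(ValueError):
            crop_resize(rng.random((10, 10)), BoundingBox(0, 0, 5, 5), (0, 5))


class TestToOriginal:
    def test_offset_only(self):
        from spinemark.geometry import CropTransform

        tf = CropTransform(offset=(3, 6), scale=(1, 1), output_size=(10, 10))
        assert np.allclose(to_original(np.array([0.0, 0.0]), tf), (3, 6))

    def test_hand_arithmetic(self):
        from spinemark.geometry import CropTransform

        tf = CropTransform(offset=(10, 10), scale=(2, 2), output_size=(10, 10))
        assert np.allclose(to_original(np.array([100.0, 40.0]), tf), (60, 30))


class TestAngles:
    def test_parallel_lines_zero(self):
        assert endplate_angle(((0, 0), (10, 5)), ((2, 7), (12, 12))) == pytest.approx(0, abs=1e-9)

    def test_slope_zero_vs_one_is_45(self):
        assert endplate_angle(((0, 0), (10, 0)), ((0, 0), (10, 10))) == pytest.approx(45, abs=1e-9)

    def test_horizontal_vs_vertical_is_90(self):
        assert endplate_angle(((0, 0), (10, 0)), ((5, 0), (5, 10))) == pytest.approx(90, abs=1e-9)

    def test_symmetric_and_order_invariant(self, rng):
        for _ in range(20):
            a = rng.uniform(0, 100, (2, 2))
            b = rng.uniform(0, 100, (2, 2))
            r = endplate_angle(a, b)
            assert r == pytest.approx(endplate_angle(b, a), abs=1e-9)
            assert r == pytest.approx(endplate_angle(a[::-1], b), abs=1e-9)
            assert 0 <= r <= 90

    def test_rigid_translation_and_scaling_invariance(self, rng):
        a = rng.uniform(0, 50, (2, 2))
        b = rng.uniform(0, 50, (2, 2))
        r = endplate_angle(a, b)
        assert endplate_angle(a * 3.7 + 11, b * 3.7 + 11) == pytest.approx(r, abs=1e-9)

    def test_coincident_points_raise(self):
        with pytest.raises(GeometryError):
            endplate_angle(((1, 1), (1, 1)), ((0, 0), (1, 0)))

    def test_sacral_slope_cases(self):
        assert sacral_slope(((0, 10), (10, 10))) == pytest.approx(0, abs=1e-9)
        assert sacral_slope(((0, 0), (10, 10))) == pytest.approx(45, abs=1e-9)
        assert sacral_slope(((0, 0), (20, 20))) == pytest.approx(45, abs=1e-9)


class TestAnglesFromCorners:
    @staticmethod
    def _level(x0, y0, slope_u, slope_d, w=30.0, h=20.0):
        return CornerSet(np.array([
            [x0 + w, y0 + w * slope_u], [x0, y0],
            [x0 + w, y0 + h + w * slope_d], [x0, y0 + h]]))

    def test_all_horizontal_gives_zeros(self):
        lmk = {
            VertebraLevel.L1: self._level(10, 10, 0, 0),
            VertebraLevel.L5: self._level(10, 100, 0, 0),
            VertebraLevel.S1: self._level(10, 140, 0, 0),
        }
        rep = angles_from_corners(lmk)
        assert rep.l1_l5 == pytest.approx(0, abs=1e-9)
        assert rep.l1_s1 == pytest.approx(0, abs=1e-9)
        assert rep.ss == pytest.approx(0, abs=1e-9)

    def test_constructed_lordosis_value(self):
        lmk = {
            VertebraLevel.L1: self._level(10, 30, -math.tan(math.radians(20)), 0),
            VertebraLevel.L5: self._level(10, 100, 0, math.tan(math.radians(16.3))),
        }
        rep = angles_from_corners(lmk)
        assert rep.l1_l5 == pytest.approx(36.3, abs=1e-9)
        assert rep.l1_s1 is None and rep.ss is None

    def test_missing_s1_yields_partial_report(self):
        lmk = {
            VertebraLevel.L1: self._level(10, 10, 0, 0),
            VertebraLevel.L5: self._level(10, 100, 0, 0),
        }
        rep = angles_from_corners(lmk)
        assert rep.l1_l5 is not None
        assert rep.l1_s1 is None and rep.ss is None
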