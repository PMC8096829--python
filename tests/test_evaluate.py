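import numpy as np
import pytest

from spinemark.annotations import CornerSet, VertebraLevel
from spinemark.evaluate import (
    REFERENCE_LEVEL_SUMMARY,
    ErrorRecord,
    angle_agreement,
    detection_accuracy,
    median_by_level,
    normalized_errors,
    pck_curve,
    weighted_median_summary,
)
from spinemark.geometry import AngleReport


def _corners(x0=10.0, y0=20.0, w=100.0, h=50.0):
    return CornerSet(np.array([
        [x0 + w, y0], [x0, y0], [x0 + w, y0 + h], [x0, y0 + h]]))


def _shifted(cs, dx=0.0, dy=0.0):
    return CornerSet(cs.points + np.array([dx, dy]), cs.valid_mask.copy())


def _s1():
    pts = np.full((4, 2), np.nan)
    pts[0] = (120.0, 200.0)
    pts[1] = (20.0, 210.0)
    return CornerSet(pts, np.array([True, True, False, False]))


class TestNormalizedErrors:
    def test_exact_prediction_gives_zero(self):
        truth = {VertebraLevel.L3: _corners()}
        recs, misses = normalized_errors(truth, truth, "i")
        assert misses == []
        assert len(recs) == 4
        assert all(r.e_x == 0 and r.e_y == 0 for r in recs)

    def test_five_px_on_100px_width_is_5_percent(self):
        truth = {VertebraLevel.L3: _corners(w=100.0)}
        pred = {VertebraLevel.L3: _shifted(truth[VertebraLevel.L3], dx=5.0)}
        recs, _ = normalized_errors(pred, truth, "i")
        assert all(r.e_x == pytest.approx(5.0) for r in recs)
        assert all(r.e_y == 0 for r in recs)

    def test_s1_contributes_only_two_records(self):
        truth = {VertebraLevel.S1: _s1()}
        pred = {VertebraLevel.S1: CornerSet(
            np.array([[121, 201], [21, 211], [50, 250], [60, 260]], float))}
        recs, _ = normalized_errors(pred, truth, "i")
        assert len(recs) == 2

    def test_missing_vertebra_is_a_miss_not_a_record(self):
        truth = {VertebraLevel.L3: _corners(), VertebraLevel.L4: _corners(y0=90)}
        pred = {VertebraLevel.L3: _corners()}
        recs, misses = normalized_errors(pred, truth, "i")
        assert misses == [VertebraLevel.L4]
        assert {r.level for r in recs} == {VertebraLevel.L3}

    def test_scale_invariance(self):
        truth = {VertebraLevel.L3: _corners()}
        pred = {VertebraLevel.L3: _shifted(truth[VertebraLevel.L3], dx=5.0, dy=2.0)}
        r1, _ = normalized_errors(pred, truth, "i")
        truth3 = {VertebraLevel.L3: CornerSet(truth[VertebraLevel.L3].points * 3)}
        pred3 = {VertebraLevel.L3: CornerSet(pred[VertebraLevel.L3].points * 3)}
        r2, _ = normalized_errors(pred3, truth3, "i")
        for a, b in zip(r1, r2):
            assert a.e_x == pytest.approx(b.e_x) and a.e_y == pytest.approx(b.e_y)


def _recs(level, exs, eys=None, width=100.0):
    eys = eys if eys is not None else exs
    return [ErrorRecord(f"img{i}", level, 0, ex, ey, ex * width / 100.0, width, width * 0.6)
            for i, (ex, ey) in enumerate(zip(exs, eys))]


class TestMedians:
    def test_midpoint_and_single_value(self):
        out = median_by_level(_recs(VertebraLevel.L2, [1.0, 3.0]))
        assert out[VertebraLevel.L2]["median_x"] == 2.0
        out = median_by_level(_recs(VertebraLevel.L2, [5.0]))
        assert out[VertebraLevel.L2]["median_x"] == 5.0

    def test_matches_sort_based_oracle(self, rng):
        vals = rng.uniform(0, 50, 101)
        out = median_by_level(_recs(VertebraLevel.L1, vals))
        assert out[VertebraLevel.L1]["median_x"] == pytest.approx(sorted(vals)[50])

    def test_counts_distinct_images(self):
        out = median_by_level(_recs(VertebraLevel.L1, [1, 2, 3]))
        assert out[VertebraLevel.L1]["n_images"] == 3
        assert out[VertebraLevel.L1]["n_corners"] == 3


class TestWeightedSummary:
    def test_single_level_identity(self):
        assert weighted_median_summary([4.2], [17]) == 4.2

    def test_reference_table_x_axis_step1(self):
        ref = REFERENCE_LEVEL_SUMMARY
        out = weighted_median_summary(ref["median_x_step1"], ref["n"])
        assert round(out, 2) == 2.20

    def test_reference_table_x_axis_step2(self):
        ref = REFERENCE_LEVEL_SUMMARY
        out = weighted_median_summary(ref["median_x_step2"], ref["n"])
        assert round(out, 2) == 1.98

    def test_empty_or_bad_counts_rejected(self):
        with pytest.raises(ValueError):
            weighted_median_summary([], [])
        with pytest.raises(ValueError):
            weighted_median_summary([1.0], [0])


class TestPck:
    def test_perfect_predictions_full_curve(self):
        out = pck_curve(_recs(VertebraLevel.L1, [0.0, 0.0]))
        assert all(v == 1.0 for v in out[VertebraLevel.L1].values())

    def test_direct_count_at_5_percent(self):
        recs = [
            ErrorRecord("a", VertebraLevel.L1, 0, 4, 4, 0.04 * 100, 100, 60),
            ErrorRecord("b", VertebraLevel.L1, 0, 6, 6, 0.06 * 100, 100, 60),
        ]
        out = pck_curve(recs)
        assert out[VertebraLevel.L1][5] == 0.5

    def test_strict_inequality_at_threshold(self):
        recs = [ErrorRecord("a", VertebraLevel.L1, 0, 5, 5, 5.0, 100, 60)]
        assert pck_curve(recs)[VertebraLevel.L1][5] == 0.0

    def test_monotone_nondecreasing_random(self, rng):
        recs = _recs(VertebraLevel.L3, rng.uniform(0, 120, 60))
        curve = pck_curve(recs)[VertebraLevel.L3]
        vals = [curve[t] for t in sorted(curve)]
        assert all(0 <= v <= 1 for v in vals)
        assert all(b >= a for a, b in zip(vals, vals[1:]))


class TestDetectionAccuracy:
    def test_all_and_half_detected(self):
        truth = {"i": {VertebraLevel.L4: None, VertebraLevel.L5: None}}
        out = detection_accuracy({"i": [VertebraLevel.L4, VertebraLevel.L5]}, truth)
        assert out["accuracy"] == 1.0
        out = detection_accuracy({"i": [VertebraLevel.L4]}, truth)
        assert out["accuracy"] == 0.5
        assert out["misses"] == [("i", VertebraLevel.L5)]

    def test_spurious_detection_counted_separately(self):
        truth = {"i": {VertebraLevel.L4: None}}
        out = detection_accuracy({"i": [VertebraLevel.L4, VertebraLevel.T9]}, truth)
        assert out["accuracy"] == 1.0
        assert out["false_positives"] == 1

    def test_zero_truth_rejected(self):
        with pytest.raises(ValueError):
            detection_accuracy({}, {})


class TestAngleAgreement:
    def test_perfect_agreement(self, rng):
        truth = [AngleReport(l1_l5=v, l1_s1=v + 10, ss=v - 5)
                 for v in rng.uniform(20, 60, 10)]
        out = angle_agreement(truth, truth)
        for key in ("L1_L5", "L1_S1", "SS"):
            assert out[key]["median_abs_error"] == 0.0
            assert out[key]["r2"] == pytest.approx(1.0)
            assert out[key]["sd_diff"] == 0.0

    def test_fraction_above_5_degrees(self):
        truth = [AngleReport(l1_l5=30.0)] * 4
        pred = [AngleReport(l1_l5=30.0 + e) for e in (2, 4, 6, 8)]
        out = angle_agreement(pred, truth)
        assert out["L1_L5"]["frac_above_threshold"] == 0.5

    def test_constant_bias_bland_altman(self, rng):
        truth = [AngleReport(ss=v) for v in rng.uniform(20, 60, 8)]
        pred = [AngleReport(ss=t.ss + 3.0) for t in truth]
        out = angle_agreement(pred, truth)
        assert out["SS"]["bland_altman_mean_diff"] == pytest.approx(3.0)
        assert out["SS"]["sd_diff"] == pytest.approx(0.0, abs=1e-9)

    def test_too_few_pairs_flagged(self):
        out = angle_agreement([AngleReport(ss=1.0)] * 2, [AngleReport(ss=2.0)] * 2)
        assert out["SS"]["r2"] is None
        assert out["L1_L5"]["n"] == 0
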