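"""Evaluation metrics: confusion counts, overlap scores, BCE, detection
AP, angle MAE reporting and the proportion confidence interval."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from curvimetry import (
    BoundingBox,
    ConfusionCounts,
    DetectionResult,
    angle_report,
    average_precision,
    bce_loss,
    ci95,
    confusion,
    dsc,
    iou,
    mae,
    map50,
    pixel_accuracy,
)

counts = st.builds(
    ConfusionCounts,
    tp=st.integers(0, 10**6),
    fp=st.integers(0, 10**6),
    tn=st.integers(0, 10**6),
    fn=st.integers(0, 10**6),
)


class TestConfusion:
    def test_identical_masks(self):
        m = np.ones((10, 10), bool)
        assert confusion(m, m) == ConfusionCounts(100, 0, 0, 0)

    def test_all_negative_prediction(self):
        gt = np.zeros((10, 10), bool)
        gt[:3, :] = True  # 30 true pixels
        c = confusion(np.zeros_like(gt), gt)
        assert c == ConfusionCounts(0, 0, 70, 30)

    def test_two_by_two_enumeration(self):
        pred = np.array([[1, 0], [0, 0]], bool)
        gt = np.array([[1, 1], [0, 0]], bool)
        assert confusion(pred, gt) == ConfusionCounts(1, 0, 2, 1)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion(np.ones((2, 2), bool), np.ones((2, 3), bool))


class TestOverlapScores:
    @pytest.mark.parametrize(
        "c, d_val, i_val, a_val",
        [
            (ConfusionCounts(100, 0, 0, 0), 1.0, 1.0, 1.0),
            (ConfusionCounts(0, 50, 0, 50), 0.0, 0.0, 0.0),
            (ConfusionCounts(1, 0, 2, 1), 2 / 3, 0.5, 0.75),
        ],
    )
    def test_point_values(self, c, d_val, i_val, a_val):
        assert dsc(c) == pytest.approx(d_val)
        assert iou(c) == pytest.approx(i_val)
        assert pixel_accuracy(c) == pytest.approx(a_val)

    def test_both_masks_empty_is_undefined(self):
        with pytest.raises(ValueError):
            dsc(ConfusionCounts(0, 0, 10, 0))
        with pytest.raises(ValueError):
            iou(ConfusionCounts(0, 0, 10, 0))

    @given(counts)
    def test_dice_jaccard_identity(self, c):
        if c.tp + c.fp + c.fn == 0:
            return
        i = iou(c)
        assert dsc(c) == pytest.approx(2 * i / (1 + i), rel=1e-12)
        assert i <= dsc(c)


class TestBCE:
    def test_perfect_prediction_is_near_zero(self):
        gt = np.array([[1, 0], [0, 1]], bool)
        assert bce_loss(gt.astype(float), gt) <= 1e-6

    def test_uniform_half_gives_ln_two(self):
        gt = np.array([[1, 0], [0, 1]], bool)
        assert bce_loss(np.full((2, 2), 0.5), gt) == pytest.approx(
            math.log(2), abs=1e-9
        )

    def test_single_pixel_closed_form(self):
        assert bce_loss(np.array([[0.25]]), np.array([[True]])) == pytest.approx(
            -math.log(0.25), abs=1e-9
        )

    @given(
        st.lists(st.floats(0.0, 1.0, allow_nan=False), min_size=1, max_size=32),
        st.lists(st.booleans(), min_size=1, max_size=32),
    )
    def test_nonnegative(self, p, y):
        n = min(len(p), len(y))
        loss = bce_loss(np.array(p[:n])[None, :], np.array(y[:n])[None, :])
        assert loss >= 0.0


def _box(x0, y0, x1, y1):
    return BoundingBox(x0, y0, x1, y1)


class TestAveragePrecision:
    def test_single_exact_detection(self):
        gt = [_box(10, 10, 50, 50)]
        det = [DetectionResult(_box(10, 10, 50, 50), 1.0)]
        assert average_precision(det, gt) == pytest.approx(1.0)

    def test_no_detections(self):
        assert average_precision([], [_box(0, 0, 5, 5)]) == 0.0

    def test_late_false_positive_does_not_hurt(self):
        # TP at conf .9 reaches recall 1 before the FP enters: AP stays 1
        gt = [_box(10, 10, 50, 50)]
        det = [
            DetectionResult(_box(10, 10, 50, 50), 0.9),
            DetectionResult(_box(200, 200, 240, 240), 0.8),
        ]
        assert average_precision(det, gt) == pytest.approx(1.0)

    def test_confidence_rescaling_invariance(self):
        gt = [_box(0, 0, 10, 10), _box(20, 20, 40, 40)]
        det = [
            DetectionResult(_box(0, 0, 10, 11), 0.8),
            DetectionResult(_box(100, 100, 120, 130), 0.6),
            DetectionResult(_box(20, 21, 40, 40), 0.4),
        ]
        scaled = [
            DetectionResult(d.predicted_box, d.confidence / 2) for d in det
        ]
        assert average_precision(det, gt) == average_precision(scaled, gt)

    def test_map_single_class_equals_mean_ap(self):
        gt = [_box(0, 0, 10, 10)]
        det = [DetectionResult(_box(0, 0, 10, 10), 1.0)]
        assert map50([(det, gt), ([], gt)]) == pytest.approx(0.5)


class TestMAEAndReport:
    @pytest.mark.parametrize(
        "est, tru, expected",
        [([1, 5], [1, 5], 0.0), ([2, 4], [1, 5], 1.0), ([80, 70], [75, 75], 5.0)],
    )
    def test_point_values(self, est, tru, expected):
        assert mae(est, tru) == pytest.approx(expected)

    @given(st.lists(st.tuples(st.floats(0, 90), st.floats(0, 90)), min_size=1))
    def test_permutation_invariance(self, pairs):
        est, tru = zip(*pairs)
        rev = list(zip(*reversed(pairs)))
        assert mae(est, tru) == pytest.approx(mae(rev[0], rev[1]))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mae([1, 2], [1])
        with pytest.raises(ValueError):
            mae([], [])

    def test_report_overall_row_pools_all_samples(self):
        # unbalanced groups: overall MAE is the pooled mean, not the
        # mean of per-group MAEs
        est = [10, 10, 10, 40]
        tru = [12, 12, 12, 50]
        rep = angle_report(est, tru)
        overall = rep.iloc[-1]
        assert overall["mae"] == pytest.approx((2 + 2 + 2 + 10) / 4)
        g10 = rep[rep["ground_truth"] == 12].iloc[0]
        assert g10["mae"] == pytest.approx(2.0)
        assert g10["n"] == 3


class TestCI95:
    @pytest.mark.parametrize("psi", [0.0, 1.0])
    def test_degenerate_proportions_have_zero_width(self, psi):
        assert ci95(psi, 50) == 0.0

    def test_half_at_hundred(self):
        assert ci95(0.5, 100) == pytest.approx(0.098, abs=1e-3)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            ci95(1.2, 10)
        with pytest.raises(ValueError):
            ci95(0.5, 0)
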