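"""Geometry, losses, detection matching, AP and the confusion report.

IoU/GIoU are checked against a pixel-rasterization oracle; AP against an
independent max-suffix-precision formula enumerated over flag sequences.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from her2fish.core import BoundingBox, SignalCounts
from her2fish.metrics import (
    LossWeights,
    MatchResult,
    average_precision,
    confusion_and_accuracy,
    detector_loss,
    giou,
    iou,
    match_detections,
    mse_loss,
    pooled_detection_ap,
)
from her2fish.models.types import Detection


# ---------------------------------------------------------------------------
# pixel-rasterization oracle for box areas (integer-coordinate boxes)

def _raster_areas(a: BoundingBox, b: BoundingBox):
    """Count pixels of A, B, their intersection/union and the enclosing box."""
    w = int(max(a.x_max, b.x_max)) + 1
    h = int(max(a.y_max, b.y_max)) + 1
    grid_a = np.zeros((h, w), dtype=bool)
    grid_b = np.zeros((h, w), dtype=bool)
    grid_a[int(a.y_min) : int(a.y_max), int(a.x_min) : int(a.x_max)] = True
    grid_b[int(b.y_min) : int(b.y_max), int(b.x_min) : int(b.x_max)] = True
    inter = np.sum(grid_a & grid_b)
    union = np.sum(grid_a | grid_b)
    cx0, cy0 = min(a.x_min, b.x_min), min(a.y_min, b.y_min)
    cx1, cy1 = max(a.x_max, b.x_max), max(a.y_max, b.y_max)
    c_area = (cx1 - cx0) * (cy1 - cy0)
    return inter, union, c_area


def _random_int_box(rng, lo=0, hi=40) -> BoundingBox:
    x0, y0 = rng.integers(lo, hi - 1, size=2)
    x1 = rng.integers(x0 + 1, hi)
    y1 = rng.integers(y0 + 1, hi)
    return BoundingBox(float(x0), float(y0), float(x1), float(y1))


class TestIoUGiou:
    def test_identical_boxes(self):
        b = BoundingBox(3, 4, 10, 12)
        assert iou(b, b) == 1.0
        assert giou(b, b) == 1.0

    def test_disjoint_boxes(self):
        assert iou(BoundingBox(0, 0, 2, 2), BoundingBox(4, 4, 6, 6)) == 0.0

    def test_partial_overlap_by_hand(self):
        a, b = BoundingBox(0, 0, 2, 2), BoundingBox(1, 1, 3, 3)
        assert iou(a, b) == pytest.approx(1 / 7)
        # enclosing box (0,0,3,3): area 9, union 7 -> penalty 2/9
        assert giou(a, b) == pytest.approx(1 / 7 - 2 / 9)

    def test_far_disjoint_giou_approaches_minus_one(self):
        a, b = BoundingBox(0, 0, 1, 1), BoundingBox(9, 9, 10, 10)
        assert giou(a, b) == pytest.approx(-0.98)

    def test_against_rasterization_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            a, b = _random_int_box(rng), _random_int_box(rng)
            inter, union, c_area = _raster_areas(a, b)
            assert iou(a, b) == pytest.approx(inter / union, abs=1e-6)
            assert giou(a, b) == pytest.approx(
                inter / union - (c_area - union) / c_area, abs=1e-6
            )
            assert giou(a, b) <= iou(a, b) + 1e-12
            assert -1.0 < giou(a, b) <= 1.0
            assert 0.0 <= iou(a, b) <= 1.0

    def test_degenerate_box_unconstructible(self):
        with pytest.raises(ValueError):
            BoundingBox(0, 0, 0, 5)


class TestMseLoss:
    @pytest.mark.parametrize(
        "pred,target,expected",
        [((3, 2), (3, 2), 0.0), ((4, 2), (2, 2), 2.0), ((0, 0), (1, 1), 1.0)],
    )
    def test_examples(self, pred, target, expected):
        assert mse_loss(SignalCounts(*pred), SignalCounts(*target)) == pytest.approx(expected)


def _det(x0, y0, x1, y1, conf) -> Detection:
    return Detection(box=BoundingBox(x0, y0, x1, y1), confidence=conf)


class TestMatchDetections:
    def test_single_exact_hit(self):
        gt = [BoundingBox(0, 0, 10, 10)]
        m = match_detections([_det(0, 0, 10, 10, 0.9)], gt, 0.5)
        assert m.flags == (True,)

    def test_double_detection_single_consumption(self):
        gt = [BoundingBox(0, 0, 10, 10)]
        m = match_detections([_det(0, 0, 10, 10, 0.9), _det(0, 0, 10, 10, 0.8)], gt, 0.5)
        assert m.flags == (True, False)

    def test_hit_miss_hit_by_hand(self):
        gt = [BoundingBox(0, 0, 10, 10), BoundingBox(20, 20, 30, 30)]
        dets = [
            _det(0, 0, 10, 10, 0.9),     # hit gt0
            _det(40, 40, 50, 50, 0.8),   # miss
            _det(20, 20, 30, 30, 0.7),   # hit gt1
        ]
        m = match_detections(dets, gt, 0.5)
        assert m.flags == (True, False, True)

    def test_input_order_invariance(self):
        gt = [BoundingBox(0, 0, 10, 10), BoundingBox(20, 20, 30, 30)]
        dets = [
            _det(0, 0, 10, 10, 0.9),
            _det(40, 40, 50, 50, 0.8),
            _det(20, 20, 30, 30, 0.7),
        ]
        m1 = match_detections(dets, gt, 0.5)
        m2 = match_detections(dets[::-1], gt, 0.5)
        assert m1 == m2

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            match_detections([], [], 1.5)

    def test_tp_bounded_by_ground_truth(self):
        with pytest.raises(ValueError):
            MatchResult(flags=(True, True), n_ground_truth=1)


def _ap_oracle(flags: tuple[bool, ...], n_gt: int) -> float:
    """Independent AP: for each TP at rank k, the best precision at rank >= k."""
    if not flags:
        return 0.0
    precisions = []
    tp = 0
    for k, f in enumerate(flags, start=1):
        tp += f
        precisions.append(tp / k)
    total = 0.0
    for k, f in enumerate(flags):
        if f:
            total += max(precisions[k:])
    return total / n_gt


class TestAveragePrecision:
    def test_perfect_ranking(self):
        m = MatchResult(flags=(True, True), n_ground_truth=2)
        assert average_precision(m) == pytest.approx(1.0)

    def test_tp_fp_tp_envelope_by_hand(self):
        m = MatchResult(flags=(True, False, True), n_ground_truth=2)
        assert average_precision(m) == pytest.approx(0.5 * 1.0 + 0.5 * (2 / 3))

    def test_single_false_positive(self):
        assert average_precision(MatchResult(flags=(False,), n_ground_truth=1)) == 0.0

    def test_zero_ground_truth_raises(self):
        with pytest.raises(ValueError):
            average_precision(MatchResult(flags=(), n_ground_truth=0))

    def test_matches_enumeration_oracle_up_to_length_12(self):
        """Exhaustive check of the precision-envelope integral (all sequences)."""
        for n in range(1, 13):
            for bits in range(2**n):
                flags = tuple(bool((bits >> i) & 1) for i in range(n))
                n_tp = sum(flags)
                for extra in (0, 2):
                    n_gt = n_tp + extra
                    if n_gt == 0:
                        continue
                    m = MatchResult(flags=flags, n_ground_truth=n_gt)
                    assert average_precision(m) == pytest.approx(
                        _ap_oracle(flags, n_gt), abs=1e-12
                    ), (flags, n_gt)


class TestPooledAp:
    def test_two_images_pooled(self):
        gts = [[BoundingBox(0, 0, 10, 10)], [BoundingBox(0, 0, 10, 10)]]
        dets = [[_det(0, 0, 10, 10, 0.9)], [_det(30, 30, 40, 40, 0.95)]]
        # global ranking: FP at 0.95 then TP at 0.9 over 2 ground truths
        expected = average_precision(MatchResult(flags=(False, True), n_ground_truth=2))
        assert pooled_detection_ap(dets, gts, 0.5) == pytest.approx(expected)


class TestConfusionAndAccuracy:
    def test_printed_arithmetic(self):
        """157/184 overall and the 117/122 reference-group row."""
        pred, ref = [], []
        # group 5 row: 117 correct, 2 -> group 2, 3 -> group 4 (122 total)
        pred += [5] * 117 + [2] * 2 + [4] * 3
        ref += [5] * 122
        # group 1 row: 38 correct, 6 each to groups 2/4/5 (56 total)
        pred += [1] * 38 + [2] * 6 + [4] * 6 + [5] * 6
        ref += [1] * 56
        # group 2: both to 5; group 3: one to 5; group 4: 2 of 3 correct
        pred += [5, 5]
        ref += [2, 2]
        pred += [5]
        ref += [3]
        pred += [4, 4, 5]
        ref += [4, 4, 4]
        confusion, overall, per_group = confusion_and_accuracy(pred, ref)
        assert confusion.sum() == 184
        assert np.trace(confusion) == 157
        assert round(100 * overall, 2) == 85.33
        assert round(100 * per_group[4], 2) == 95.90
        assert round(100 * per_group[0], 2) == 67.86

    def test_row_sums_match_reference_counts(self):
        rng = np.random.default_rng(3)
        ref = rng.integers(1, 6, size=200).tolist()
        pred = rng.integers(1, 6, size=200).tolist()
        confusion, overall, _ = confusion_and_accuracy(pred, ref)
        for g in range(1, 6):
            assert confusion[g - 1].sum() == ref.count(g)
        assert overall == pytest.approx(np.trace(confusion) / 200)

    def test_errors(self):
        with pytest.raises(ValueError, match="length"):
            confusion_and_accuracy([1], [1, 2])
        with pytest.raises(ValueError, match="empty"):
            confusion_and_accuracy([], [])
        with pytest.raises(ValueError, match="1..5"):
            confusion_and_accuracy([6], [1])


class TestDetectorLoss:
    def test_perfect_predictions_vanish(self):
        b = BoundingBox(0, 0, 10, 10)
        obj = np.array([1.0, 0.0, 0.0, 0.0])
        t_obj = np.array([1.0, 0.0, 0.0, 0.0])
        loss = detector_loss([b], [b], obj, t_obj, pred_class=np.array([1.0]))
        assert loss == pytest.approx(0.0, abs=1e-9)

    def test_giou_term_from_overlap_example(self):
        a, b = BoundingBox(0, 0, 2, 2), BoundingBox(1, 1, 3, 3)
        loss = detector_loss(
            [a], [b], np.zeros(0), np.zeros(0),
            weights=LossWeights(giou=1.0, objectness=0.0, classification=0.0),
        )
        assert loss == pytest.approx(1 + 5 / 63)

    def test_empty_targets_with_silent_objectness(self):
        loss = detector_loss([], [], np.zeros(8), np.zeros(8))
        assert loss == pytest.approx(0.0, abs=1e-9)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            detector_loss([], [], np.zeros(3), np.zeros(4))
        with pytest.raises(ValueError):
            detector_loss([BoundingBox(0, 0, 1, 1)], [], np.zeros(1), np.zeros(1))

    @given(data=st.data())
    @settings(max_examples=50, derandomize=True)
    def test_non_negative_for_non_negative_weights(self, data):
        rng_seed = data.draw(st.integers(0, 10_000))
        rng = np.random.default_rng(rng_seed)
        n = int(rng.integers(0, 4))
        preds = [_random_int_box(rng) for _ in range(n)]
        targets = [_random_int_box(rng) for _ in range(n)]
        obj = rng.uniform(0, 1, size=6)
        t_obj = (rng.uniform(size=6) > 0.7).astype(float)
        loss = detector_loss(preds, targets, obj, t_obj, pred_class=rng.uniform(0, 1, n))
        assert loss >= 0.0
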