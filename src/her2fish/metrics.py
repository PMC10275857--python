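"""Geometric and statistical evaluation utilities.

Covers box overlap (IoU and generalized IoU), the two training losses
(detector composite loss and count-regression MSE), ranked detection
matching, average precision under the all-point precision envelope, and the
five-group confusion matrix / accuracy report.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Sequence

import numpy as np

from .core import AscoCapGroup, BoundingBox, SignalCounts

if TYPE_CHECKING:  # pragma: no cover
    from .models.types import Detection

__all__ = [
    "MatchResult",
    "EvalReport",
    "LossWeights",
    "iou",
    "giou",
    "detector_loss",
    "mse_loss",
    "match_detections",
    "average_precision",
    "pooled_detection_ap",
    "confusion_and_accuracy",
]


def _intersection_area(a: BoundingBox, b: BoundingBox) -> float:
    iw = min(a.x_max, b.x_max) - max(a.x_min, b.x_min)
    ih = min(a.y_max, b.y_max) - max(a.y_min, b.y_min)
    if iw <= 0 or ih <= 0:
        return 0.0
    return iw * ih


def iou(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection over union of two boxes; 0 when disjoint, 1 when identical."""
    inter = _intersection_area(a, b)
    union = a.area + b.area - inter
    return inter / union


def giou(a: BoundingBox, b: BoundingBox) -> float:
    """Generalized IoU: IoU minus the enclosing-box penalty ``|C \\ (A u B)| / |C|``.

    Unlike plain IoU, remains informative (negative) for disjoint boxes; range
    (-1, 1], equal to IoU whenever the smallest enclosing box C is the union.
    """
    inter = _intersection_area(a, b)
    union = a.area + b.area - inter
    cw = max(a.x_max, b.x_max) - min(a.x_min, b.x_min)
    ch = max(a.y_max, b.y_max) - min(a.y_min, b.y_min)
    c_area = cw * ch
    return inter / union - (c_area - union) / c_area


def mse_loss(predicted: SignalCounts, target: SignalCounts) -> float:
    """Mean squared error over the two signal channels of one nucleus."""
    return 0.5 * ((predicted.her2 - target.her2) ** 2 + (predicted.cep17 - target.cep17) ** 2)


@dataclass(frozen=True)
class LossWeights:
    """Relative weights of the three detector loss terms (defaults all 1.0).

    ``obj_pos_weight`` up-weights positive anchors inside the objectness
    binary cross-entropy; with thousands of background anchors per handful
    of nuclei the unweighted mean otherwise drowns the positives.
    """

    giou: float = 1.0
    objectness: float = 1.0
    classification: float = 1.0
    obj_pos_weight: float = 1.0

    def __post_init__(self) -> None:
        for name in ("giou", "objectness", "classification", "obj_pos_weight"):
            if getattr(self, name) < 0:
                raise ValueError(f"loss weight {name} must be >= 0")


def _bce(p: np.ndarray, t: np.ndarray) -> np.ndarray:
    p = np.clip(p, 1e-12, 1.0 - 1e-12)
    return -(t * np.log(p) + (1.0 - t) * np.log1p(-p))


def detector_loss(
    pred_boxes: Sequence[BoundingBox],
    target_boxes: Sequence[BoundingBox],
    pred_objectness: np.ndarray,
    target_objectness: np.ndarray,
    pred_class: np.ndarray | None = None,
    weights: LossWeights = LossWeights(),
) -> float:
    """Composite detector loss: (1 - GIoU) + objectness BCE + classification CE.

    ``pred_boxes`` and ``target_boxes`` are the matched pairs (aligned, one
    target per positive anchor); ``pred_objectness`` / ``target_objectness``
    are probabilities over *all* anchors; ``pred_class`` holds the single
    tumour-cell-nucleus class probability on the positive anchors (the
    classification term is degenerate with one class but kept for fidelity
    to the detector's head).  Non-negative for non-negative weights.
    """
    if len(pred_boxes) != len(target_boxes):
        raise ValueError(
            f"matched box count mismatch: {len(pred_boxes)} predictions vs "
            f"{len(target_boxes)} targets"
        )
    pred_objectness = np.asarray(pred_objectness, dtype=float)
    target_objectness = np.asarray(target_objectness, dtype=float)
    if pred_objectness.shape != target_objectness.shape:
        raise ValueError(
            f"objectness shape mismatch: {pred_objectness.shape} vs {target_objectness.shape}"
        )

    box_term = 0.0
    if pred_boxes:
        box_term = float(np.mean([1.0 - giou(p, t) for p, t in zip(pred_boxes, target_boxes)]))

    obj_term = 0.0
    if pred_objectness.size:
        w = np.where(target_objectness > 0.5, weights.obj_pos_weight, 1.0)
        obj_term = float(np.mean(w * _bce(pred_objectness, target_objectness)))

    cls_term = 0.0
    if pred_class is not None and np.size(pred_class):
        pred_class = np.asarray(pred_class, dtype=float)
        cls_term = float(np.mean(_bce(pred_class, np.ones_like(pred_class))))

    return weights.giou * box_term + weights.objectness * obj_term + weights.classification * cls_term


@dataclass(frozen=True)
class MatchResult:
    """TP/FP flags for ranked detections against a ground-truth box set.

    ``flags`` is ordered by descending detection confidence; True marks a
    true positive.  At most ``n_ground_truth`` flags are True and each
    ground-truth box is matched at most once.
    """

    flags: tuple[bool, ...]
    n_ground_truth: int

    def __post_init__(self) -> None:
        if self.n_ground_truth < 0:
            raise ValueError("n_ground_truth must be >= 0")
        if sum(self.flags) > self.n_ground_truth:
            raise ValueError("more true positives than ground-truth boxes")


def match_detections(
    detections: Sequence["Detection"],
    ground_truths: Sequence[BoundingBox],
    iou_threshold: float = 0.5,
) -> MatchResult:
    """Greedily match ranked detections to ground-truth boxes.

    Detections are sorted by descending confidence (ties broken by input
    index); each is a true positive if its best-IoU *unmatched* ground truth
    reaches ``iou_threshold``, consuming that ground truth, else a false
    positive.
    """
    if not 0.0 <= iou_threshold <= 1.0:
        raise ValueError(f"iou_threshold must be in [0, 1], got {iou_threshold}")
    order = sorted(range(len(detections)), key=lambda i: (-detections[i].confidence, i))
    unmatched = set(range(len(ground_truths)))
    flags: list[bool] = []
    for i in order:
        det = detections[i]
        best_iou, best_j = 0.0, None
        for j in unmatched:
            v = iou(det.box, ground_truths[j])
            if v > best_iou:
                best_iou, best_j = v, j
        if best_j is not None and best_iou >= iou_threshold:
            unmatched.discard(best_j)
            flags.append(True)
        else:
            flags.append(False)
    return MatchResult(flags=tuple(flags), n_ground_truth=len(ground_truths))


def average_precision(match: MatchResult) -> float:
    """Area under the all-point precision envelope as a function of recall.

    With the single tumour-cell-nucleus class, mAP equals this AP.  Raises
    on an empty ground-truth set (recall undefined).
    """
    if match.n_ground_truth == 0:
        raise ValueError("average precision undefined with zero ground truths")
    if not match.flags:
        return 0.0
    tp = np.cumsum(np.asarray(match.flags, dtype=float))
    fp = np.cumsum(1.0 - np.asarray(match.flags, dtype=float))
    recall = tp / match.n_ground_truth
    precision = tp / (tp + fp)
    # all-point interpolation: precision envelope (running max from the right)
    r = np.concatenate(([0.0], recall))
    p = np.concatenate(([1.0], precision))
    p = np.maximum.accumulate(p[::-1])[::-1]
    return float(np.sum((r[1:] - r[:-1]) * p[1:]))


def pooled_detection_ap(
    detections_per_image: Sequence[Sequence["Detection"]],
    ground_truths_per_image: Sequence[Sequence[BoundingBox]],
    iou_threshold: float = 0.5,
) -> float:
    """Dataset-level AP: per-image greedy matching, globally ranked by confidence.

    The standard pooled protocol: each image's detections are matched to its
    own ground truth in confidence order, then all (confidence, flag) pairs
    are ranked globally and integrated against the total ground-truth count.
    """
    if len(detections_per_image) != len(ground_truths_per_image):
        raise ValueError("per-image detection and ground-truth lists differ in length")
    n_gt = sum(len(g) for g in ground_truths_per_image)
    if n_gt == 0:
        raise ValueError("average precision undefined with zero ground truths")
    scored: list[tuple[float, int, bool]] = []
    for img_idx, (dets, gts) in enumerate(zip(detections_per_image, ground_truths_per_image)):
        order = sorted(range(len(dets)), key=lambda i: (-dets[i].confidence, i))
        flags = match_detections(dets, list(gts), iou_threshold).flags
        for rank, i in enumerate(order):
            scored.append((dets[i].confidence, img_idx, flags[rank]))
    scored.sort(key=lambda t: (-t[0], t[1]))
    return average_precision(
        MatchResult(flags=tuple(f for _, _, f in scored), n_ground_truth=n_gt)
    )


@dataclass(frozen=True)
class EvalReport:
    """Detection + classification evaluation summary.

    ``confusion`` rows index the reference (pathologist/ground-truth) group,
    columns the predicted group; ``n_failed`` counts images with an explicit
    failure status, which enter the accuracy denominators as
    misclassifications but not the 5x5 matrix.
    """

    map: float
    confusion: np.ndarray
    overall_accuracy: float
    per_group_accuracy: tuple[float, ...]
    n_failed: int = 0

    def to_record(self) -> dict:
        return {
            "map": self.map,
            "confusion": self.confusion.astype(int).tolist(),
            "overall_accuracy": self.overall_accuracy,
            "per_group_accuracy": [
                None if np.isnan(a) else a for a in self.per_group_accuracy
            ],
            "n_failed": self.n_failed,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_record())

    def confusion_to_csv(self, path) -> None:
        rows = [["ref\\pred"] + [f"group{g}" for g in range(1, 6)]]
        for g, row in enumerate(self.confusion.astype(int).tolist(), start=1):
            rows.append([f"group{g}"] + [str(v) for v in row])
        with open(path, "w") as fh:
            fh.write("\n".join(",".join(r) for r in rows) + "\n")


def confusion_and_accuracy(
    predicted_groups: Sequence[AscoCapGroup | int],
    reference_groups: Sequence[AscoCapGroup | int],
) -> tuple[np.ndarray, float, tuple[float, ...]]:
    """5x5 confusion matrix plus overall and per-reference-group accuracy.

    Rows are reference groups 1-5, columns predicted groups; overall
    accuracy is trace/total, per-group accuracy is the row-normalized
    diagonal (NaN for groups absent from the reference).
    """
    if len(predicted_groups) != len(reference_groups):
        raise ValueError(
            f"length mismatch: {len(predicted_groups)} predictions vs "
            f"{len(reference_groups)} references"
        )
    if not reference_groups:
        raise ValueError("empty group sequences")
    confusion = np.zeros((5, 5), dtype=int)
    for p, r in zip(predicted_groups, reference_groups):
        p, r = int(p), int(r)
        if not (1 <= p <= 5 and 1 <= r <= 5):
            raise ValueError(f"groups must be in 1..5, got predicted={p}, reference={r}")
        confusion[r - 1, p - 1] += 1
    total = confusion.sum()
    overall = float(np.trace(confusion) / total)
    row_totals = confusion.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        per_group = np.where(row_totals > 0, np.diag(confusion) / row_totals, np.nan)
    return confusion, overall, tuple(float(a) for a in per_group)
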