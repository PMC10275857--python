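"""End-to-end orchestration: image -> detections -> counts -> group.

``run_pipeline`` applies stage 1 (nucleus detection) and stage 2
(per-nucleus signal counting) with independently selectable backends —
``classical`` (deterministic image processing) or ``learned`` (trained
convolutional models) — then aggregates to the image-level summary and
2018 ASCO/CAP group.  Degenerate outcomes are first-class: an image with
no detected nuclei or no CEP17 signal yields an explicit failure status,
never a silent group.  ``evaluate_run`` scores a set of predictions
against a manifest: pooled detection mAP, 5x5 group confusion matrix and
overall / per-group accuracy, with failed images counted as
misclassifications.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .core import (
    BoundingBox,
    ImageSummary,
    NoCep17SignalsError,
    SignalCounts,
    summarize_image,
)
from .manifest import read_manifest, write_manifest
from .metrics import EvalReport, confusion_and_accuracy, pooled_detection_ap
from .models import (
    CounterModel,
    Detection,
    DetectorModel,
    classical_count,
    classical_detect,
    crop_patch,
    detect_nuclei,
    predict_counts,
)
from .simgen import load_image

__all__ = [
    "RunConfig",
    "PredictionRecord",
    "run_pipeline",
    "evaluate_run",
    "read_manifest",
    "write_manifest",
]

logger = logging.getLogger("her2fish")

STATUS_OK = "ok"
STATUS_NO_NUCLEI = "no_nuclei"
STATUS_NO_CEP17 = "no_cep17"


@dataclass
class RunConfig:
    """Per-stage backend selection plus thresholds and paths."""

    detect_backend: str = "classical"  # classical | learned
    count_backend: str = "classical"
    detector_path: str | None = None
    counter_path: str | None = None
    conf_threshold: float = 0.5
    nms_iou: float = 0.45
    blue_threshold: float = 0.15
    min_area: float = 50.0
    max_area: float | None = None
    peak_rel_threshold: float = 0.5
    min_separation: int = 2
    patch_size: int = 80
    patch_pad_frac: float = 0.15
    case_level: bool = False
    out_dir: str | None = None
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        for name in ("detect_backend", "count_backend"):
            v = getattr(self, name)
            if v not in ("classical", "learned"):
                raise ValueError(f"{name} must be 'classical' or 'learned', got {v!r}")
        if self.detect_backend == "learned" and not self.detector_path:
            raise ValueError("learned detect backend requires detector_path")
        if self.count_backend == "learned" and not self.counter_path:
            raise ValueError("learned count backend requires counter_path")
        for name in ("detector_path", "counter_path"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise ValueError(f"{name} does not exist: {p}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


@dataclass
class PredictionRecord:
    """One image's full prediction: detections, per-nucleus counts, summary.

    ``summary`` is None exactly when ``status`` is a failure; the stored
    summary is always reproducible from the stored per-nucleus counts.
    """

    image_id: str
    status: str
    detections: list[tuple[Detection, SignalCounts]] = field(default_factory=list)
    summary: ImageSummary | None = None

    def resummarize(self) -> ImageSummary:
        return summarize_image([c for _, c in self.detections])

    def to_record(self) -> dict:
        return {
            "image_id": self.image_id,
            "status": self.status,
            "detections": [
                {
                    "box": list(d.box.as_tuple()),
                    "confidence": d.confidence,
                    "her2": c.her2,
                    "cep17": c.cep17,
                }
                for d, c in self.detections
            ],
            "summary": self.summary.to_record() if self.summary else None,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_record())

    @classmethod
    def from_record(cls, rec: Mapping) -> "PredictionRecord":
        detections = [
            (
                Detection(box=BoundingBox(*d["box"]), confidence=d["confidence"]),
                SignalCounts(her2=d["her2"], cep17=d["cep17"]),
            )
            for d in rec["detections"]
        ]
        summary = ImageSummary.from_record(rec["summary"]) if rec["summary"] else None
        return cls(
            image_id=rec["image_id"], status=rec["status"],
            detections=detections, summary=summary,
        )


class _ModelCache:
    def __init__(self):
        self.detector: DetectorModel | None = None
        self.counter: CounterModel | None = None


def _detect(image: np.ndarray, config: RunConfig, cache: _ModelCache) -> list[Detection]:
    if config.detect_backend == "classical":
        return classical_detect(
            image,
            min_area=config.min_area,
            max_area=config.max_area,
            blue_threshold=config.blue_threshold,
        )
    if cache.detector is None:
        cache.detector = DetectorModel.load(config.detector_path)
    return detect_nuclei(
        image, cache.detector, conf_threshold=config.conf_threshold, nms_iou=config.nms_iou
    )


def _count(image: np.ndarray, det: Detection, config: RunConfig, cache: _ModelCache) -> SignalCounts:
    if config.count_backend == "classical":
        # native-resolution crop, no pad: keeps neighbouring nuclei's signals out
        patch = crop_patch(image, det.box, pad=0.0, out_size=None)
        return classical_count(
            patch,
            peak_rel_threshold=config.peak_rel_threshold,
            min_separation=config.min_separation,
        )
    if cache.counter is None:
        cache.counter = CounterModel.load(config.counter_path)
    pad = config.patch_pad_frac * max(det.box.width, det.box.height)
    patch = crop_patch(image, det.box, pad=pad, out_size=config.patch_size)
    return predict_counts(cache.counter, patch)


def run_pipeline(
    image, config: RunConfig, image_id: str | None = None, _cache: _ModelCache | None = None
) -> PredictionRecord:
    """Run detection, per-nucleus counting and image-level aggregation.

    ``image`` is a path or an (H, W, 3) float RGB array.  Classical and
    learned backends are interchangeable per stage and produce structurally
    identical records.
    """
    if isinstance(image, (str, Path)):
        image_id = image_id or Path(image).stem
        image = load_image(image)
    image_id = image_id or "image"
    cache = _cache or _ModelCache()

    detections = _detect(image, config, cache)
    if not detections:
        logger.warning("%s: no nuclei detected", image_id)
        return PredictionRecord(image_id=image_id, status=STATUS_NO_NUCLEI)
    counted = [(d, _count(image, d, config, cache)) for d in detections]
    try:
        summary = summarize_image([c for _, c in counted])
    except NoCep17SignalsError:
        logger.warning("%s: no CEP17 signals counted", image_id)
        return PredictionRecord(image_id=image_id, status=STATUS_NO_CEP17, detections=counted)
    return PredictionRecord(
        image_id=image_id, status=STATUS_OK, detections=counted, summary=summary
    )


def run_manifest(
    manifest_path, config: RunConfig, case_pooling: bool | None = None
) -> dict[str, PredictionRecord]:
    """Run the pipeline over every image of a manifest (shared model cache)."""
    entries = read_manifest(manifest_path)
    cache = _ModelCache()
    records = {}
    for e in entries:
        records[e.id] = run_pipeline(e.resolved_path, config, image_id=e.id, _cache=cache)
    return records


def pool_records_as_case(records: Sequence[PredictionRecord]) -> ImageSummary:
    """Optional case-level reducer: sum per-nucleus counts across images."""
    counts = [c for r in records for _, c in r.detections]
    return summarize_image(counts)


def evaluate_run(
    manifest_path, predictions: Mapping[str, PredictionRecord], iou_threshold: float = 0.5
) -> EvalReport:
    """Score predictions against a manifest's ground truth.

    Detection quality is the pooled mAP at ``iou_threshold`` over all
    manifest boxes; classification quality is the 5x5 confusion matrix and
    accuracies over images whose manifest group is defined.  Images with a
    failure-status prediction count against overall and per-group accuracy
    but cannot enter the matrix.
    """
    entries = read_manifest(manifest_path)
    if not entries:
        raise ValueError("empty manifest")
    missing = [e.id for e in entries if e.id not in predictions]
    if missing:
        raise ValueError(f"missing predictions for images: {missing}")

    dets_per_image, gts_per_image = [], []
    pred_groups, ref_groups = [], []
    n_failed = 0
    failed_by_ref = np.zeros(5, dtype=int)
    for e in entries:
        rec = predictions[e.id]
        dets_per_image.append([d for d, _ in rec.detections])
        gts_per_image.append([a.box for a in e.annotations])
        if e.group is None:
            continue
        if rec.status == STATUS_OK:
            pred_groups.append(int(rec.summary.group))
            ref_groups.append(e.group)
        else:
            n_failed += 1
            failed_by_ref[e.group - 1] += 1

    map_value = pooled_detection_ap(dets_per_image, gts_per_image, iou_threshold)

    if pred_groups:
        confusion, _, _ = confusion_and_accuracy(pred_groups, ref_groups)
    else:
        confusion = np.zeros((5, 5), dtype=int)
    row_totals = confusion.sum(axis=1) + failed_by_ref
    total = row_totals.sum()
    overall = float(np.trace(confusion) / total) if total else float("nan")
    with np.errstate(invalid="ignore", divide="ignore"):
        per_group = np.where(row_totals > 0, np.diag(confusion) / row_totals, np.nan)
    return EvalReport(
        map=float(map_value),
        confusion=confusion,
        overall_accuracy=overall,
        per_group_accuracy=tuple(float(a) for a in per_group),
        n_failed=n_failed,
    )
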