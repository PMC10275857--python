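"""Dataset manifest reading/writing with schema validation.

A manifest is a JSON file ``{"split": ..., "images": [...]}`` where each
image record carries its path (relative to the manifest), pixel size, box
annotations with integer HER2/CEP17 counts, and the ground-truth-derived
ASCO/CAP group (or null when undefined).  Validation errors name the
offending field path, e.g. ``images[3].annotations[1].her2``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from .core import BoundingBox
from .simgen import BoxAnnotation

__all__ = ["ManifestImage", "ManifestError", "read_manifest", "write_manifest"]


class ManifestError(ValueError):
    """Schema violation in a dataset manifest, naming the field path."""


@dataclass
class ManifestImage:
    id: str
    path: str
    width: int
    height: int
    annotations: list[BoxAnnotation] = field(default_factory=list)
    group: int | None = None
    resolved_path: Path | None = None

    def to_record(self) -> dict:
        return {
            "id": self.id,
            "path": self.path,
            "width": self.width,
            "height": self.height,
            "annotations": [a.to_record() for a in self.annotations],
            "group": self.group,
        }


def _check(cond: bool, where: str, message: str) -> None:
    if not cond:
        raise ManifestError(f"{where}: {message}")


def read_manifest(path) -> list[ManifestImage]:
    """Parse and validate a manifest; returns one entry per image."""
    path = Path(path)
    try:
        with open(path) as fh:
            data = json.load(fh)
    except json.JSONDecodeError as exc:
        raise ManifestError(f"{path}: malformed JSON ({exc})") from exc
    _check(isinstance(data, dict) and "images" in data, str(path), "missing 'images' key")
    images = data["images"]
    _check(isinstance(images, list), "images", "must be a list")
    entries = []
    seen_ids: set[str] = set()
    for i, rec in enumerate(images):
        where = f"images[{i}]"
        _check(isinstance(rec, dict), where, "must be an object")
        for key in ("id", "path", "width", "height", "annotations"):
            _check(key in rec, f"{where}.{key}", "missing")
        _check(rec["id"] not in seen_ids, f"{where}.id", f"duplicate id {rec['id']!r}")
        seen_ids.add(rec["id"])
        w, h = rec["width"], rec["height"]
        _check(isinstance(w, int) and w > 0, f"{where}.width", f"must be a positive int, got {w!r}")
        _check(isinstance(h, int) and h > 0, f"{where}.height", f"must be a positive int, got {h!r}")
        annotations = []
        for j, a in enumerate(rec["annotations"]):
            awhere = f"{where}.annotations[{j}]"
            for key in ("x_min", "y_min", "x_max", "y_max", "her2", "cep17"):
                _check(key in a, f"{awhere}.{key}", "missing")
            for key in ("her2", "cep17"):
                v = a[key]
                _check(
                    isinstance(v, int) and v >= 0,
                    f"{awhere}.{key}",
                    f"annotated counts must be non-negative integers, got {v!r}",
                )
            try:
                box = BoundingBox(a["x_min"], a["y_min"], a["x_max"], a["y_max"])
            except ValueError as exc:
                raise ManifestError(f"{awhere}: invalid box ({exc})") from exc
            _check(
                box.x_max <= w and box.y_max <= h,
                awhere,
                f"box {box.as_tuple()} exceeds image bounds {w}x{h}",
            )
            annotations.append(BoxAnnotation(box=box, her2=a["her2"], cep17=a["cep17"]))
        group = rec.get("group")
        if group is not None:
            _check(group in (1, 2, 3, 4, 5), f"{where}.group", f"must be 1..5 or null, got {group!r}")
        entries.append(
            ManifestImage(
                id=str(rec["id"]),
                path=str(rec["path"]),
                width=w,
                height=h,
                annotations=annotations,
                group=group,
                resolved_path=path.parent / rec["path"],
            )
        )
    return entries


def write_manifest(path, entries: list[ManifestImage], split: str | None = None) -> None:
    """Write a manifest; ``read_manifest`` of the result round-trips."""
    data: dict = {"images": [e.to_record() for e in entries]}
    if split is not None:
        data["split"] = split
    with open(path, "w") as fh:
        json.dump(data, fh, indent=1)
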