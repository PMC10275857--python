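"""Domain types and image-level HER2 FISH arithmetic.

A dual-probe HER2 FISH image yields, per tumour-cell nucleus, a count of
HER2 gene signals (SpectrumOrange, rendered red here) and of CEP17
chromosome-17 centromere signals (SpectrumGreen).  The image-level readout
is the average HER2 copy number (total HER2 signals / nuclei counted) and
the HER2/CEP17 ratio (total HER2 / total CEP17), which the 2018 ASCO/CAP
guideline partitions into five diagnostic groups:

==========  ============  =====================
Group       HER2/CEP17    mean HER2 copies
==========  ============  =====================
1           >= 2.0        >= 4.0   (amplified)
2           >= 2.0        <  4.0
3           <  2.0        >= 6.0
4           <  2.0        4.0 - <6.0
5           <  2.0        <  4.0   (not amplified)
==========  ============  =====================

All thresholds are inclusive on the ``>=`` side.  Classification always
uses unrounded values; two-decimal rounding (round-half-to-even) is applied
only for display.
"""

from __future__ import annotations

import csv
import enum
import json
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

__all__ = [
    "BoundingBox",
    "SignalCounts",
    "ImageSummary",
    "AscoCapGroup",
    "NoNucleiError",
    "NoCep17SignalsError",
    "average_copy_number",
    "her2_cep17_ratio",
    "classify_group",
    "summarize_image",
    "write_summary_csv",
]


class NoNucleiError(ValueError):
    """Raised when an image-level summary is requested with zero nuclei."""


class NoCep17SignalsError(ValueError):
    """Raised when the HER2/CEP17 ratio is undefined (no CEP17 signals)."""


def _require_finite(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value):
        raise ValueError(f"{name} must be finite, got {value!r}")
    return value


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned pixel box, 0-based, half-open: area = (x_max-x_min)*(y_max-y_min)."""

    x_min: float
    y_min: float
    x_max: float
    y_max: float

    def __post_init__(self) -> None:
        for name in ("x_min", "y_min", "x_max", "y_max"):
            v = _require_finite(name, getattr(self, name))
            if v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")
            object.__setattr__(self, name, v)
        if not (self.x_min < self.x_max and self.y_min < self.y_max):
            raise ValueError(
                f"degenerate box: ({self.x_min}, {self.y_min}, {self.x_max}, {self.y_max})"
            )

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min

    @property
    def area(self) -> float:
        return self.width * self.height

    @property
    def center(self) -> tuple[float, float]:
        return (0.5 * (self.x_min + self.x_max), 0.5 * (self.y_min + self.y_max))

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.x_min, self.y_min, self.x_max, self.y_max)


@dataclass(frozen=True)
class SignalCounts:
    """Per-nucleus HER2 and CEP17 signal counts.

    Annotated (ground-truth) counts are integers; regressed counts are
    non-negative reals and are accepted without rounding.
    """

    her2: float
    cep17: float

    def __post_init__(self) -> None:
        for name in ("her2", "cep17"):
            v = _require_finite(name, getattr(self, name))
            if v < 0:
                raise ValueError(f"{name} count must be non-negative, got {v}")
            object.__setattr__(self, name, v)


class AscoCapGroup(enum.IntEnum):
    """2018 ASCO/CAP HER2 FISH group (1 = classically amplified, 5 = not amplified)."""

    GROUP1 = 1
    GROUP2 = 2
    GROUP3 = 3
    GROUP4 = 4
    GROUP5 = 5


def average_copy_number(total_signals: float, n_nuclei: int) -> float:
    """Mean signals per nucleus: ``total_signals / n_nuclei``.

    Raises :class:`NoNucleiError` when ``n_nuclei`` is zero.
    """
    total_signals = _require_finite("total_signals", total_signals)
    if total_signals < 0:
        raise ValueError(f"total_signals must be >= 0, got {total_signals}")
    if n_nuclei < 1:
        raise NoNucleiError("no nuclei detected: average copy number undefined")
    return total_signals / n_nuclei


def her2_cep17_ratio(total_her2: float, total_cep17: float) -> float:
    """HER2/CEP17 ratio: total HER2 signals divided by total CEP17 signals.

    Works equally on totals or on per-nucleus averages (the nucleus count
    cancels).  Raises :class:`NoCep17SignalsError` when no CEP17 signal was
    counted, in which case the ratio is undefined.
    """
    total_her2 = _require_finite("total_her2", total_her2)
    total_cep17 = _require_finite("total_cep17", total_cep17)
    if total_her2 < 0 or total_cep17 < 0:
        raise ValueError("signal totals must be non-negative")
    if total_cep17 == 0:
        raise NoCep17SignalsError("no CEP17 signals: HER2/CEP17 ratio undefined")
    return total_her2 / total_cep17


def classify_group(avg_her2: float, ratio: float) -> AscoCapGroup:
    """Assign the 2018 ASCO/CAP five-group FISH status.

    Parameters are the *unrounded* mean HER2 copy number per nucleus and the
    *unrounded* HER2/CEP17 ratio.  The five rules partition the plane, so
    exactly one group is returned; all thresholds (2.0, 4.0, 6.0) are
    inclusive on the ``>=`` side.
    """
    avg_her2 = _require_finite("avg_her2", avg_her2)
    ratio = _require_finite("ratio", ratio)
    if avg_her2 < 0 or ratio < 0:
        raise ValueError("avg_her2 and ratio must be non-negative")
    if ratio >= 2.0:
        return AscoCapGroup.GROUP1 if avg_her2 >= 4.0 else AscoCapGroup.GROUP2
    if avg_her2 >= 6.0:
        return AscoCapGroup.GROUP3
    if avg_her2 >= 4.0:
        return AscoCapGroup.GROUP4
    return AscoCapGroup.GROUP5


def _round2(x: float) -> float:
    # Python's round() is round-half-to-even, matching display convention.
    return round(x, 2)


@dataclass(frozen=True)
class ImageSummary:
    """Image-level aggregate over the counted nuclei of one FISH image."""

    n_nuclei: int
    total_her2: float
    total_cep17: float
    avg_her2: float
    avg_cep17: float
    ratio: float
    group: AscoCapGroup

    def rounded(self) -> dict[str, float]:
        """Two-decimal display values (classification is never based on these)."""
        return {
            "avg_her2": _round2(self.avg_her2),
            "avg_cep17": _round2(self.avg_cep17),
            "ratio": _round2(self.ratio),
        }

    def to_record(self) -> dict:
        """Flat JSON-serializable record."""
        return {
            "n_nuclei": self.n_nuclei,
            "total_her2": self.total_her2,
            "total_cep17": self.total_cep17,
            "avg_her2": self.avg_her2,
            "avg_cep17": self.avg_cep17,
            "ratio": self.ratio,
            "group": int(self.group),
        }

    def to_json(self) -> str:
        return json.dumps(self.to_record())

    @classmethod
    def from_record(cls, record: Mapping) -> "ImageSummary":
        return cls(
            n_nuclei=int(record["n_nuclei"]),
            total_her2=float(record["total_her2"]),
            total_cep17=float(record["total_cep17"]),
            avg_her2=float(record["avg_her2"]),
            avg_cep17=float(record["avg_cep17"]),
            ratio=float(record["ratio"]),
            group=AscoCapGroup(int(record["group"])),
        )

    @classmethod
    def from_json(cls, s: str) -> "ImageSummary":
        return cls.from_record(json.loads(s))


def summarize_image(per_nucleus_counts: Sequence[SignalCounts]) -> ImageSummary:
    """Aggregate per-nucleus counts into the image-level FISH readout.

    Totals are sums over nuclei; averages divide by the nucleus count; the
    ratio is total HER2 over total CEP17 (identically avg/avg); the group is
    classified from the unrounded average and ratio.

    Raises :class:`NoNucleiError` on an empty list and
    :class:`NoCep17SignalsError` when the CEP17 total is zero.
    """
    counts = list(per_nucleus_counts)
    if not counts:
        raise NoNucleiError("no nuclei detected: cannot summarize image")
    n = len(counts)
    total_her2 = float(sum(c.her2 for c in counts))
    total_cep17 = float(sum(c.cep17 for c in counts))
    avg_her2 = average_copy_number(total_her2, n)
    avg_cep17 = average_copy_number(total_cep17, n)
    ratio = her2_cep17_ratio(total_her2, total_cep17)
    group = classify_group(avg_her2, ratio)
    return ImageSummary(
        n_nuclei=n,
        total_her2=total_her2,
        total_cep17=total_cep17,
        avg_her2=avg_her2,
        avg_cep17=avg_cep17,
        ratio=ratio,
        group=group,
    )


def write_summary_csv(path, summaries: Iterable[tuple[str, ImageSummary]]) -> None:
    """Write one display-rounded CSV row per image.

    ``summaries`` yields ``(image_id, ImageSummary)`` pairs; columns are
    image_id, n_nuclei, avg_her2, avg_cep17, ratio, group.
    """
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["image_id", "n_nuclei", "avg_her2", "avg_cep17", "ratio", "group"])
        for image_id, s in summaries:
            r = s.rounded()
            writer.writerow(
                [image_id, s.n_nuclei, f"{r['avg_her2']:.2f}", f"{r['avg_cep17']:.2f}",
                 f"{r['ratio']:.2f}", int(s.group)]
            )
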