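"""Deterministic classical backends for both pipeline stages.

These are transparent image-processing baselines that serve as exact
oracles on clean synthetic fields: nuclei are found by thresholding the
DAPI (blue) channel and labelling connected components; signals are
counted per channel as local intensity maxima above a relative threshold.
Their failure modes deliberately mirror the clinical ones — heavily
overlapping nuclei merge into one detection, and fused HER2 signal
clusters are undercounted — which makes them useful for directional
artefact tests as well.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage.measure import label, regionprops

from ..core import BoundingBox, SignalCounts
from .types import Detection, NucleusPatch

__all__ = ["classical_detect", "classical_count"]

#: Channels below this absolute intensity are treated as background-only.
BACKGROUND_FLOOR = 0.2


def classical_detect(
    image: np.ndarray,
    min_area: float = 50.0,
    max_area: float | None = None,
    blue_threshold: float = 0.15,
) -> list[Detection]:
    """Detect nuclei as connected components of the thresholded blue channel.

    Components outside ``[min_area, max_area]`` pixels squared are dropped;
    every returned detection carries confidence 1.0.  May return an empty
    list (blank image); heavily overlapping nuclei can merge into a single
    component — a documented limitation shared with clinical material.
    """
    blue = image[:, :, 2]
    labelled = label(blue > blue_threshold)
    detections = []
    for region in regionprops(labelled):
        if region.area < min_area:
            continue
        if max_area is not None and region.area > max_area:
            continue
        y0, x0, y1, x1 = region.bbox
        detections.append(
            Detection(box=BoundingBox(float(x0), float(y0), float(x1), float(y1)),
                      confidence=1.0)
        )
    detections.sort(key=lambda d: (d.box.y_min, d.box.x_min))
    return detections


def _count_channel(
    channel: np.ndarray, peak_rel_threshold: float, min_separation: int
) -> int:
    peak = float(channel.max()) if channel.size else 0.0
    if peak < BACKGROUND_FLOOR:
        return 0
    threshold = max(BACKGROUND_FLOOR, peak_rel_threshold * peak)
    size = 2 * int(min_separation) + 1
    is_max = (channel >= ndimage.maximum_filter(channel, size=size)) & (channel >= threshold)
    # plateau regions count once (saturated clusters, 8-bit quantization ties);
    # 8-connectivity so diagonal ties of a single peak are not split
    _, n = ndimage.label(is_max, structure=np.ones((3, 3), dtype=bool))
    return int(n)


def classical_count(
    patch: NucleusPatch | np.ndarray,
    peak_rel_threshold: float = 0.5,
    min_separation: int = 2,
) -> SignalCounts:
    """Count signals per channel as separated local maxima above half-peak.

    Red maxima give the HER2 count, green maxima the CEP17 count; a channel
    whose maximum stays below the absolute background floor counts zero.
    Fused signal clusters are undercounted by construction (one blob, one
    maximum).
    """
    raster = patch.raster if isinstance(patch, NucleusPatch) else patch
    if not 0.0 <= peak_rel_threshold <= 1.0:
        raise ValueError(f"peak_rel_threshold must be in [0, 1], got {peak_rel_threshold}")
    her2 = _count_channel(raster[:, :, 0], peak_rel_threshold, min_separation)
    cep17 = _count_channel(raster[:, :, 1], peak_rel_threshold, min_separation)
    return SignalCounts(her2=her2, cep17=cep17)
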