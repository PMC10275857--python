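"""Synthetic dual-probe FISH image generator with exact ground truth.

Emulates the image regime of clinically scanned HER2 FISH fields: a dark
background, elliptical DAPI-counterstained nuclei in the blue channel, and
punctate Gaussian-profile hybridization signals inside each nucleus — HER2
in red (SpectrumOrange) and CEP17 in green.  Each rendered nucleus carries
an exact bounding-box annotation with the planted signal counts, so
detector, counter and end-to-end pipeline are testable without clinical
data.

Clean images are constructed to be *resolvable*: nuclei keep a clearance
margin from each other and spots keep a minimum separation, so that a
deterministic local-maxima counter recovers the planted counts exactly.
Artefact flags deliberately break resolvability to reproduce documented
clinical failure modes: fused HER2 signal clusters, weak or coarse CEP17
signals, and overlapping nuclei.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from PIL import Image

from .core import BoundingBox, SignalCounts, summarize_image

__all__ = [
    "SyntheticSpec",
    "BoxAnnotation",
    "GenerationError",
    "render_fish_image",
    "make_dataset",
    "split_sizes",
    "spec_for_group",
    "save_image",
    "load_image",
]

# Nucleus centres must be at least NUCLEUS_CLEARANCE * (R1 + R2) apart
# (scaled down by the allowed overlap fraction); spots sit within
# SPOT_MAX_ECCENTRICITY of the nucleus radius and keep the separation
# below.  Together these guarantee that every planted spot is a distinct
# local maximum of its own box and that no spot of one nucleus bleeds a
# countable maximum into a neighbour's box.
NUCLEUS_CLEARANCE = 1.3
SPOT_MAX_ECCENTRICITY = 0.7
#: packing-safety factor when sizing a nucleus to its sampled spot count
SPOT_PACK_FACTOR = 2.5


def _spot_min_distance(r1: float, r2: float) -> float:
    """Centre distance keeping two Gaussian spots (sigma = r/2) resolvable."""
    return max(4.0, 1.25 * (r1 + r2))


class GenerationError(RuntimeError):
    """Raised when nuclei or spots cannot be placed within the retry budget."""


@dataclass(frozen=True)
class SyntheticSpec:
    """Parametric description of one simulated FISH field.

    Count and size parameters are inclusive ``(low, high)`` ranges sampled
    uniformly per nucleus/spot.  Intensities are in [0, 1].  The artefact
    flags reproduce the failure modes seen in clinical material: fused HER2
    clusters, weak or coarse CEP17 signals, and overlapping nuclei (as an
    allowed overlap fraction of the clearance distance).
    """

    image_size: tuple[int, int] = (512, 512)
    n_nuclei: tuple[int, int] = (5, 25)
    nucleus_radius: tuple[float, float] = (20.0, 40.0)
    her2_count: tuple[int, int] = (1, 30)
    cep17_count: tuple[int, int] = (1, 6)
    her2_spot_radius: tuple[float, float] = (2.0, 4.0)
    cep17_spot_radius: tuple[float, float] = (2.0, 4.0)
    her2_peak: tuple[float, float] = (0.7, 1.0)
    cep17_peak: tuple[float, float] = (0.7, 1.0)
    nucleus_intensity: tuple[float, float] = (0.35, 0.6)
    background_noise: float = 0.02
    her2_clustering: bool = False
    weak_cep17: bool = False
    coarse_cep17: bool = False
    nucleus_overlap: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("n_nuclei", "her2_count", "cep17_count"):
            lo, hi = getattr(self, name)
            if lo < 0 or hi < lo:
                raise ValueError(f"{name} range invalid: {(lo, hi)}")
        for name in ("her2_peak", "cep17_peak", "nucleus_intensity"):
            lo, hi = getattr(self, name)
            if not (0.0 <= lo <= hi <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]: {(lo, hi)}")
        if not 0.0 <= self.nucleus_overlap <= 1.0:
            raise ValueError(f"nucleus_overlap must be in [0, 1]: {self.nucleus_overlap}")
        if self.background_noise < 0:
            raise ValueError("background_noise must be >= 0")


@dataclass(frozen=True)
class BoxAnnotation:
    """Ground-truth nucleus box with its planted integer signal counts."""

    box: BoundingBox
    her2: int
    cep17: int

    def __post_init__(self) -> None:
        if self.her2 < 0 or self.cep17 < 0:
            raise ValueError("annotated counts must be non-negative integers")

    @property
    def counts(self) -> SignalCounts:
        return SignalCounts(her2=self.her2, cep17=self.cep17)

    def to_record(self) -> dict:
        b = self.box
        return {
            "x_min": b.x_min, "y_min": b.y_min, "x_max": b.x_max, "y_max": b.y_max,
            "her2": self.her2, "cep17": self.cep17,
        }

    @classmethod
    def from_record(cls, r: dict) -> "BoxAnnotation":
        return cls(
            box=BoundingBox(r["x_min"], r["y_min"], r["x_max"], r["y_max"]),
            her2=int(r["her2"]),
            cep17=int(r["cep17"]),
        )


def _uniform(rng: np.random.Generator, rng_pair: tuple[float, float]) -> float:
    lo, hi = rng_pair
    return float(rng.uniform(lo, hi)) if hi > lo else float(lo)


def _int_uniform(rng: np.random.Generator, rng_pair: tuple[int, int]) -> int:
    lo, hi = rng_pair
    return int(rng.integers(lo, hi + 1))


def _capacity_radius(spot_plan: list[tuple[int, tuple[float, float]]]) -> float:
    """Circular-nucleus radius whose usable area packs the planned spots.

    ``spot_plan`` lists (count, radius_range) per channel.  Each spot claims
    a disc of half its minimum resolvable distance; the usable region is the
    inner SPOT_MAX_ECCENTRICITY of the nucleus, and SPOT_PACK_FACTOR leaves
    headroom for random sequential placement.
    """
    claim = 0.0
    for count, (lo, hi) in spot_plan:
        r_mid = 0.5 * (lo + hi)
        d = _spot_min_distance(r_mid, r_mid)
        claim += count * math.pi * (d / 2.0) ** 2
    return math.sqrt(SPOT_PACK_FACTOR * claim / math.pi) / SPOT_MAX_ECCENTRICITY


def _place_nucleus(rng: np.random.Generator, spec: SyntheticSpec, placed: list,
                   min_radius: float):
    """Sample one ellipse subject to clearance; radius floor from spot capacity."""
    h, w = spec.image_size[1], spec.image_size[0]
    lo, hi = spec.nucleus_radius
    lo = max(lo, min_radius)
    hi = max(hi, min_radius)
    for attempt in range(400):
        a = _uniform(rng, (lo, hi))
        b = _uniform(rng, (lo, hi))
        if attempt > 200:  # congested field: fall back to smallest nuclei
            a = b = lo
        theta = float(rng.uniform(0, math.pi))
        big = max(a, b)
        if 2 * big + 4 >= min(w, h):
            continue
        cx = float(rng.uniform(big + 2, w - big - 2))
        cy = float(rng.uniform(big + 2, h - big - 2))
        min_gap_scale = NUCLEUS_CLEARANCE * (1.0 - spec.nucleus_overlap)
        if all(
            math.hypot(cx - px, cy - py) >= min_gap_scale * (big + pR)
            for px, py, _, _, _, pR in placed
        ):
            return (cx, cy, a, b, theta, big)
    raise GenerationError(
        f"could not place nucleus {len(placed) + 1} within the overlap budget"
    )


def _place_spots(
    rng: np.random.Generator,
    nucleus,
    n_spots: int,
    radius_range: tuple[float, float],
    peak_range: tuple[float, float],
    existing: list,
    enforce_separation: bool,
) -> list:
    """Sample spot centres inside the nucleus ellipse; returns (x, y, r, peak)."""
    cx, cy, a, b, theta, _ = nucleus
    ct, st = math.cos(theta), math.sin(theta)
    spots = []
    for _ in range(n_spots):
        ok = False
        for attempt in range(450):
            r = _uniform(rng, radius_range)
            ecc = SPOT_MAX_ECCENTRICITY
            if attempt > 150:
                r = radius_range[0]
            if attempt > 300:
                ecc = min(1.07 * SPOT_MAX_ECCENTRICITY, 0.8)
            u = ecc * math.sqrt(rng.uniform())
            phi = rng.uniform(0, 2 * math.pi)
            ex, ey = u * a * math.cos(phi), u * b * math.sin(phi)
            x = cx + ct * ex - st * ey
            y = cy + st * ex + ct * ey
            if enforce_separation and not all(
                math.hypot(x - sx, y - sy) >= _spot_min_distance(r, sr)
                for sx, sy, sr, _ in existing + spots
            ):
                continue
            spots.append((x, y, r, _uniform(rng, peak_range)))
            ok = True
            break
        if not ok:
            raise GenerationError(
                f"could not place {n_spots} spots inside nucleus at ({cx:.0f}, {cy:.0f})"
            )
    return spots


def _render_gaussian_spot(channel: np.ndarray, x: float, y: float, r: float, peak: float) -> None:
    """Add a truncated isotropic Gaussian (sigma = r / 2) centred at (x, y)."""
    sigma = r / 2.0
    ext = int(math.ceil(3 * sigma)) + 1
    h, w = channel.shape
    x0, x1 = max(0, int(x) - ext), min(w, int(x) + ext + 1)
    y0, y1 = max(0, int(y) - ext), min(h, int(y) + ext + 1)
    if x0 >= x1 or y0 >= y1:
        return
    xs = np.arange(x0, x1, dtype=float)
    ys = np.arange(y0, y1, dtype=float)
    g = peak * np.exp(
        -(((ys[:, None] - y) ** 2) + ((xs[None, :] - x) ** 2)) / (2 * sigma**2)
    )
    channel[y0:y1, x0:x1] += g


def _ellipse_mask_and_box(shape, cx, cy, a, b, theta):
    """Soft-edged ellipse intensity profile and its exact axis-aligned box."""
    h, w = shape
    hx = math.sqrt((a * math.cos(theta)) ** 2 + (b * math.sin(theta)) ** 2)
    hy = math.sqrt((a * math.sin(theta)) ** 2 + (b * math.cos(theta)) ** 2)
    x0, x1 = max(0, int(math.floor(cx - hx))), min(w, int(math.ceil(cx + hx)) + 1)
    y0, y1 = max(0, int(math.floor(cy - hy))), min(h, int(math.ceil(cy + hy)) + 1)
    xs = np.arange(x0, x1, dtype=float) - cx
    ys = np.arange(y0, y1, dtype=float) - cy
    ct, st = math.cos(theta), math.sin(theta)
    u = (xs[None, :] * ct + ys[:, None] * st) / a
    v = (-xs[None, :] * st + ys[:, None] * ct) / b
    e = u**2 + v**2
    profile = np.clip((1.0 - e) * 4.0, 0.0, 1.0)  # soft 25% rim, flat interior
    box = BoundingBox(
        float(max(0, math.floor(cx - hx))),
        float(max(0, math.floor(cy - hy))),
        float(min(w, math.ceil(cx + hx))),
        float(min(h, math.ceil(cy + hy))),
    )
    return profile, (y0, y1, x0, x1), box


def render_fish_image(
    spec: SyntheticSpec, seed: int | None = None
) -> tuple[np.ndarray, list[BoxAnnotation]]:
    """Render one synthetic FISH field and its exact ground truth.

    Returns an (H, W, 3) float RGB image in [0, 1] (red = HER2, green =
    CEP17, blue = DAPI) and one :class:`BoxAnnotation` per nucleus.  Fully
    deterministic given ``(spec, seed)``; ``seed`` overrides ``spec.seed``.
    """
    if seed is None:
        seed = spec.seed if spec.seed is not None else 0
    rng = np.random.default_rng(seed)
    w, h = spec.image_size
    image = np.zeros((h, w, 3), dtype=np.float64)

    n_nuclei = _int_uniform(rng, spec.n_nuclei)
    placed: list = []
    annotations: list[BoxAnnotation] = []
    for _ in range(n_nuclei):
        # counts first: the nucleus is sized so its spots stay resolvable
        n_her2 = _int_uniform(rng, spec.her2_count)
        n_cep17 = _int_uniform(rng, spec.cep17_count)
        if spec.her2_clustering:
            her2_plan = (min(3, max(1, n_her2)), tuple(3 * r for r in spec.her2_spot_radius))
        else:
            her2_plan = (n_her2, spec.her2_spot_radius)
        min_radius = _capacity_radius([her2_plan, (n_cep17, spec.cep17_spot_radius)])
        try:
            nucleus = _place_nucleus(rng, spec, placed, min_radius)
        except GenerationError:
            if len(placed) >= spec.n_nuclei[0] and placed:
                break  # field saturated beyond the guaranteed minimum
            raise
        placed.append(nucleus)

        cx, cy, a, b, theta, _ = nucleus
        profile, (y0, y1, x0, x1), box = _ellipse_mask_and_box((h, w), cx, cy, a, b, theta)
        intensity = _uniform(rng, spec.nucleus_intensity)
        image[y0:y1, x0:x1, 2] = np.maximum(image[y0:y1, x0:x1, 2], intensity * profile)

        if spec.her2_clustering and n_her2 > 1:
            her2_spots = _clustered_spots(rng, nucleus, n_her2, spec)
        else:
            her2_spots = _place_spots(
                rng, nucleus, n_her2, spec.her2_spot_radius, spec.her2_peak,
                existing=[], enforce_separation=True,
            )

        cep_radius = spec.cep17_spot_radius
        cep_peak = spec.cep17_peak
        if spec.coarse_cep17:
            cep_radius = (2 * cep_radius[0], 2 * cep_radius[1])
        if spec.weak_cep17:
            cep_peak = (0.25 * cep_peak[0], 0.25 * cep_peak[1])
        cep_spots = _place_spots(
            rng, nucleus, n_cep17, cep_radius, cep_peak,
            existing=her2_spots if not spec.her2_clustering else [],
            enforce_separation=not (spec.coarse_cep17 or spec.weak_cep17),
        )

        for x, y, r, peak in her2_spots:
            _render_gaussian_spot(image[:, :, 0], x, y, r, peak)
        for x, y, r, peak in cep_spots:
            _render_gaussian_spot(image[:, :, 1], x, y, r, peak)
        annotations.append(BoxAnnotation(box=box, her2=n_her2, cep17=n_cep17))

    if spec.background_noise > 0:
        image += rng.normal(0.0, spec.background_noise, size=image.shape)
    np.clip(image, 0.0, 1.0, out=image)
    return image, annotations


def _clustered_spots(rng, nucleus, n_spots: int, spec: SyntheticSpec) -> list:
    """HER2 cluster artefact: spots fused around 1-3 cluster centres."""
    n_clusters = int(rng.integers(1, min(3, n_spots) + 1))
    centres = _place_spots(
        rng, nucleus, n_clusters,
        (3 * spec.her2_spot_radius[0], 3 * spec.her2_spot_radius[1]),
        spec.her2_peak, existing=[], enforce_separation=True,
    )
    spots = []
    for i in range(n_spots):
        cx, cy, cr, _ = centres[i % n_clusters]
        r = _uniform(rng, spec.her2_spot_radius)
        ang = rng.uniform(0, 2 * math.pi)
        d = rng.uniform(0, 0.5 * r)  # well inside a spot radius: signals fuse
        spots.append((cx + d * math.cos(ang), cy + d * math.sin(ang), r,
                      _uniform(rng, spec.her2_peak)))
    return spots


def save_image(path, image: np.ndarray, jpeg_quality: int = 95) -> None:
    """Write a float [0,1] RGB raster as PNG (lossless) or JPEG (quality 95)."""
    arr = np.clip(np.round(image * 255.0), 0, 255).astype(np.uint8)
    im = Image.fromarray(arr, mode="RGB")
    path = Path(path)
    if path.suffix.lower() in (".jpg", ".jpeg"):
        im.save(path, quality=jpeg_quality)
    else:
        im.save(path)


def load_image(path) -> np.ndarray:
    """Read an RGB image file to float [0,1], shape (H, W, 3)."""
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"), dtype=np.float64) / 255.0


def split_sizes(n: int, fractions: Sequence[float]) -> tuple[int, ...]:
    """Largest-remainder apportionment of ``n`` items into splits.

    Guarantees the sizes sum to ``n`` while each is within one of
    ``n * fraction`` — e.g. 918 at (0.6002, 0.1994, 0.2004) gives
    (551, 183, 184).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    fractions = [float(f) for f in fractions]
    if any(f < 0 for f in fractions) or abs(sum(fractions) - 1.0) > 1e-6:
        raise ValueError(f"split fractions must be non-negative and sum to 1: {fractions}")
    raw = [n * f for f in fractions]
    sizes = [int(math.floor(r)) for r in raw]
    remainder = n - sum(sizes)
    order = sorted(range(len(fractions)), key=lambda i: raw[i] - sizes[i], reverse=True)
    for i in order[:remainder]:
        sizes[i] += 1
    return tuple(sizes)


#: Per-group count ranges that force each 2018 ASCO/CAP group by construction.
_GROUP_COUNT_RANGES = {
    1: ((8, 14), (1, 3)),   # ratio >= 2.67, avg >= 8
    2: ((3, 3), (1, 1)),    # ratio 3, avg 3
    3: ((6, 7), (4, 6)),    # ratio <= 1.75, avg >= 6
    4: ((4, 5), (3, 4)),    # ratio <= 1.67, avg in [4, 5]
    5: ((2, 3), (2, 3)),    # ratio <= 1.5, avg <= 3
}


def spec_for_group(group: int, base: SyntheticSpec = SyntheticSpec()) -> SyntheticSpec:
    """Derive a spec whose per-nucleus count ranges guarantee one ASCO/CAP group."""
    her2, cep17 = _GROUP_COUNT_RANGES[int(group)]
    return dataclasses.replace(base, her2_count=her2, cep17_count=cep17)


def make_dataset(
    spec: SyntheticSpec | Sequence[SyntheticSpec],
    n_images: int,
    split_fractions: Sequence[float],
    seed: int,
    out_dir,
    image_format: str = "png",
) -> dict:
    """Render ``n_images`` synthetic fields and write train/val/test manifests.

    Multiple specs are cycled round-robin across images (e.g. one spec per
    ASCO/CAP group for a balanced dataset).  Every image lands in exactly
    one split; each split gets a JSON manifest listing image path, size,
    box annotations and the ground-truth-derived group.  Returns
    ``{split: manifest_path}``.
    """
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    specs = [spec] if isinstance(spec, SyntheticSpec) else list(spec)
    sizes = split_sizes(n_images, split_fractions)
    out_dir = Path(out_dir)
    image_dir = out_dir / "images"
    image_dir.mkdir(parents=True, exist_ok=True)

    seeds = np.random.SeedSequence(seed).generate_state(n_images) & 0x7FFFFFFF
    entries = []
    for i in range(n_images):
        sp = specs[i % len(specs)]
        image, annotations = render_fish_image(sp, int(seeds[i]))
        name = f"img_{i:05d}.{image_format}"
        save_image(image_dir / name, image)
        try:
            group = int(summarize_image([a.counts for a in annotations]).group)
        except ValueError:  # no nuclei or no CEP17 signal: group undefined
            group = None
        entries.append(
            {
                "id": f"img_{i:05d}",
                "path": str(Path("images") / name),
                "width": sp.image_size[0],
                "height": sp.image_size[1],
                "annotations": [a.to_record() for a in annotations],
                "group": group,
            }
        )

    manifests: dict[str, Path] = {}
    offset = 0
    for split, size in zip(("train", "val", "test"), sizes):
        manifest = {"split": split, "images": entries[offset : offset + size]}
        offset += size
        mpath = out_dir / f"{split}.json"
        with open(mpath, "w") as fh:
            json.dump(manifest, fh, indent=1)
        manifests[split] = mpath
    return manifests
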