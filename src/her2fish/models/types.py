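"""Shared model-facing domain types."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..core import BoundingBox
from ..metrics import LossWeights

CLASS_LABEL = "tumour cell nucleus"


@dataclass(frozen=True)
class Detection:
    """One detected nucleus: box, confidence, and the (single) class label."""

    box: BoundingBox
    confidence: float
    label: str = CLASS_LABEL

    def __post_init__(self) -> None:
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError(f"confidence must be in [0, 1], got {self.confidence}")


@dataclass(frozen=True)
class NucleusPatch:
    """A nucleus crop with the geometry to map patch coords back to the image.

    ``raster`` is (H, W, 3) float RGB; a source-image point ``p`` maps to
    patch coordinates ``(p - origin) * scale`` per axis.
    """

    raster: np.ndarray
    origin: tuple[float, float]
    scale: tuple[float, float]
    source_box: BoundingBox

    def to_patch_coords(self, x: float, y: float) -> tuple[float, float]:
        return ((x - self.origin[0]) * self.scale[0], (y - self.origin[1]) * self.scale[1])


@dataclass
class TrainConfig:
    """Training hyperparameters shared by detector and counter.

    The optimizer is Adam with a fixed learning rate of 1e-3 (not decayed).
    Augmentation applies axis-aligned flips, 90-degree rotations and small
    integer translations, all label-consistent.  ``pretrained_weights`` is a
    hook for loading an external checkpoint before training; by default
    initialization is random.
    """

    epochs: int = 10
    batch_size: int = 8
    learning_rate: float = 1e-3
    augment: bool = True
    seed: int = 0
    # the three loss terms keep weight 1.0; positive anchors are up-weighted
    # inside the objectness BCE so foreground is not drowned by background
    loss_weights: LossWeights = field(default_factory=lambda: LossWeights(obj_pos_weight=100.0))
    anchors: list[tuple[float, float]] | None = None
    input_size: int = 416
    patch_size: int = 80
    patch_pad_frac: float = 0.15
    eval_conf_threshold: float = 0.1
    pretrained_weights: str | None = None

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be > 0")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
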