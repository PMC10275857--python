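"""Anchor-based single-class nucleus detector.

A compact fully-convolutional detector in the family of three-scale
anchor-box predictors: a strided backbone produces feature maps at strides
8, 16 and 32; a 1x1 head at each scale predicts, per anchor, box offsets
(tx, ty, tw, th), an objectness logit and a (degenerate, single-class)
classification logit.  Anchor shapes come from IoU k-means over the
training boxes.  Training minimizes the composite loss — (1 - GIoU) on
matched boxes, objectness binary cross-entropy over all anchors,
classification cross-entropy on positives — with Adam at a fixed learning
rate of 1e-3, all gradients hand-derived.

The backbone is deliberately depth-configurable: the default is a small
stack sized for CPU training on synthetic fields; wider/deeper variants
are a config choice, and ``TrainConfig.pretrained_weights`` hooks in an
external checkpoint when one is available.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from skimage.transform import resize as _sk_resize

from ..core import BoundingBox
from ..metrics import LossWeights, pooled_detection_ap
from . import nn
from .types import Detection, TrainConfig

__all__ = [
    "DetectorConfig",
    "DetectorModel",
    "cluster_anchor_boxes",
    "detect_nuclei",
    "train_detector",
    "letterbox",
    "nms",
]

STRIDES = (8, 16, 32)


# ---------------------------------------------------------------------------
# anchors

def _wh_iou(wh1: np.ndarray, wh2: np.ndarray) -> np.ndarray:
    """Shape IoU of origin-centred boxes; wh1 (n,2) vs wh2 (k,2) -> (n,k)."""
    inter = np.minimum(wh1[:, None, 0], wh2[None, :, 0]) * np.minimum(
        wh1[:, None, 1], wh2[None, :, 1]
    )
    a1 = wh1[:, 0] * wh1[:, 1]
    a2 = wh2[:, 0] * wh2[:, 1]
    return inter / (a1[:, None] + a2[None, :] - inter)


def cluster_anchor_boxes(
    annotation_boxes, k: int = 9, max_iter: int = 100
) -> list[tuple[float, float]]:
    """K-means over box (width, height) with distance 1 - IoU at the origin.

    Deterministic: initialized from area quantiles of the input boxes.
    Returns ``k`` anchors sorted by non-increasing area; with ``k`` a
    multiple of 3 the first third belongs to the coarsest scale (stride 32)
    and the last third to the finest (stride 8).
    """
    wh = np.array(
        [
            (b.width, b.height) if isinstance(b, BoundingBox) else (float(b[0]), float(b[1]))
            for b in annotation_boxes
        ],
        dtype=float,
    )
    if len(wh) < k:
        raise ValueError(f"need at least k={k} boxes to cluster, got {len(wh)}")
    order = np.argsort(wh[:, 0] * wh[:, 1])
    centre_idx = np.linspace(0, len(wh) - 1, k).round().astype(int)
    centres = wh[order[centre_idx]].copy()
    assign = np.full(len(wh), -1)
    for _ in range(max_iter):
        new_assign = np.argmax(_wh_iou(wh, centres), axis=1)
        if np.array_equal(new_assign, assign):
            break
        assign = new_assign
        for j in range(k):
            members = wh[assign == j]
            if len(members):
                centres[j] = members.mean(axis=0)
            else:  # re-seed an empty cluster at the worst-covered box
                worst = np.argmin(_wh_iou(wh, centres).max(axis=1))
                centres[j] = wh[worst]
    areas = centres[:, 0] * centres[:, 1]
    centres = centres[np.argsort(-areas)]
    return [(float(w), float(h)) for w, h in centres]


# ---------------------------------------------------------------------------
# model

@dataclass
class DetectorConfig:
    """Architecture + anchor configuration (embedded in checkpoints)."""

    input_size: int = 416
    widths: tuple[int, ...] = (8, 16, 24, 32, 48, 64)
    anchors: list[tuple[float, float]] = field(default_factory=list)  # 9 (w,h), area desc
    n_classes: int = 1
    seed: int = 0

    def anchors_per_scale(self) -> list[list[tuple[float, float]]]:
        """Anchors grouped per stride (8, 16, 32): finest scale gets the smallest."""
        a = self.anchors
        if len(a) != 9:
            raise ValueError(f"expected 9 anchors, got {len(a)}")
        return [list(a[6:9]), list(a[3:6]), list(a[0:3])]


class DetectorModel:
    """Three-scale anchor detector with explicit forward/backward."""

    def __init__(self, config: DetectorConfig):
        if not config.anchors:
            raise ValueError("detector requires anchors (cluster them from training boxes)")
        self.config = config
        w = config.widths
        rng = np.random.default_rng(config.seed)
        head_ch = 3 * (5 + config.n_classes)
        self.seg1 = nn.Sequential(
            nn.Conv2d(3, w[0], 3, 1, rng=rng), nn.LeakyReLU(),
            nn.Conv2d(w[0], w[1], 3, 2, rng=rng), nn.LeakyReLU(),
            nn.Conv2d(w[1], w[2], 3, 2, rng=rng), nn.LeakyReLU(),
            nn.Conv2d(w[2], w[3], 3, 2, rng=rng), nn.LeakyReLU(),
            nn.Conv2d(w[3], w[3], 3, 1, rng=rng), nn.LeakyReLU(),
        )
        self.seg2 = nn.Sequential(
            nn.Conv2d(w[3], w[4], 3, 2, rng=rng), nn.LeakyReLU(),
            nn.Conv2d(w[4], w[4], 3, 1, rng=rng), nn.LeakyReLU(),
        )
        self.seg3 = nn.Sequential(
            nn.Conv2d(w[4], w[5], 3, 2, rng=rng), nn.LeakyReLU(),
            nn.Conv2d(w[5], w[5], 3, 1, rng=rng), nn.LeakyReLU(),
        )
        self.heads = [
            nn.Conv2d(w[3], head_ch, 1, 1, rng=rng),
            nn.Conv2d(w[4], head_ch, 1, 1, rng=rng),
            nn.Conv2d(w[5], head_ch, 1, 1, rng=rng),
        ]

    def params(self) -> list[nn.Param]:
        ps = self.seg1.params() + self.seg2.params() + self.seg3.params()
        for h in self.heads:
            ps += h.params()
        return ps

    def forward(self, x: np.ndarray, train: bool = False) -> list[np.ndarray]:
        f1 = self.seg1.forward(x, train)
        f2 = self.seg2.forward(f1, train)
        f3 = self.seg3.forward(f2, train)
        return [
            self.heads[0].forward(f1, train),
            self.heads[1].forward(f2, train),
            self.heads[2].forward(f3, train),
        ]

    def backward(self, grads: list[np.ndarray]) -> None:
        d3 = self.heads[2].backward(grads[2])
        d2 = self.heads[1].backward(grads[1]) + self.seg3.backward(d3)
        d1 = self.heads[0].backward(grads[0]) + self.seg2.backward(d2)
        self.seg1.backward(d1)

    # -- persistence -------------------------------------------------------
    def save(self, path) -> None:
        arrays = {f"p{i}": p.value for i, p in enumerate(self.params())}
        cfg = dict(
            input_size=self.config.input_size,
            widths=list(self.config.widths),
            anchors=[list(a) for a in self.config.anchors],
            n_classes=self.config.n_classes,
            seed=self.config.seed,
            kind="detector",
            schema=1,
        )
        np.savez(path, _config=np.frombuffer(json.dumps(cfg).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path) -> "DetectorModel":
        with np.load(path) as data:
            cfg = json.loads(bytes(data["_config"]).decode())
            if cfg.get("kind") != "detector":
                raise ValueError(f"{path} is not a detector checkpoint")
            model = cls(
                DetectorConfig(
                    input_size=cfg["input_size"],
                    widths=tuple(cfg["widths"]),
                    anchors=[tuple(a) for a in cfg["anchors"]],
                    n_classes=cfg["n_classes"],
                    seed=cfg["seed"],
                )
            )
            for i, p in enumerate(model.params()):
                p.value[...] = data[f"p{i}"]
        return model


# ---------------------------------------------------------------------------
# geometry helpers

def letterbox(image: np.ndarray, size: int) -> tuple[np.ndarray, float, float, float]:
    """Resize keeping aspect ratio and pad to ``size`` x ``size``.

    Returns (padded image, scale, pad_x, pad_y); an image point p maps to
    ``p * scale + pad``.
    """
    h, w = image.shape[:2]
    if h == size and w == size:
        return image, 1.0, 0.0, 0.0
    scale = size / max(h, w)
    nh, nw = int(round(h * scale)), int(round(w * scale))
    resized = _sk_resize(image, (nh, nw), order=1, anti_aliasing=False, preserve_range=True)
    out = np.zeros((size, size, image.shape[2]), dtype=image.dtype)
    pad_y, pad_x = (size - nh) // 2, (size - nw) // 2
    out[pad_y : pad_y + nh, pad_x : pad_x + nw] = resized
    return out, scale, float(pad_x), float(pad_y)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def decode_outputs(
    raw_maps: list[np.ndarray], config: DetectorConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Decode raw head maps (batch size 1) to (boxes (N,4) px, confidences (N,))."""
    all_boxes, all_conf = [], []
    for raw, stride, anchors in zip(raw_maps, STRIDES, config.anchors_per_scale()):
        _, ch, hh, ww = raw.shape
        v = raw[0].reshape(3, ch // 3, hh, ww).astype(np.float64)
        gx = np.arange(ww)[None, None, :]
        gy = np.arange(hh)[None, :, None]
        bx = (gx + _sigmoid(v[:, 0])) * stride
        by = (gy + _sigmoid(v[:, 1])) * stride
        aw = np.array([a[0] for a in anchors])[:, None, None]
        ah = np.array([a[1] for a in anchors])[:, None, None]
        bw = aw * np.exp(np.clip(v[:, 2], -8, 8))
        bh = ah * np.exp(np.clip(v[:, 3], -8, 8))
        conf = _sigmoid(v[:, 4]) * _sigmoid(v[:, 5])
        boxes = np.stack(
            [bx - bw / 2, by - bh / 2, bx + bw / 2, by + bh / 2], axis=-1
        ).reshape(-1, 4)
        all_boxes.append(boxes)
        all_conf.append(conf.reshape(-1))
    return np.concatenate(all_boxes), np.concatenate(all_conf)


def _box_iou_matrix(boxes: np.ndarray) -> np.ndarray:
    x1, y1, x2, y2 = boxes.T
    areas = (x2 - x1) * (y2 - y1)
    iw = np.clip(np.minimum(x2[:, None], x2[None, :]) - np.maximum(x1[:, None], x1[None, :]), 0, None)
    ih = np.clip(np.minimum(y2[:, None], y2[None, :]) - np.maximum(y1[:, None], y1[None, :]), 0, None)
    inter = iw * ih
    return inter / (areas[:, None] + areas[None, :] - inter + 1e-12)


def nms(boxes: np.ndarray, confidences: np.ndarray, iou_threshold: float) -> list[int]:
    """Greedy non-maximum suppression; returns surviving indices, conf-descending."""
    order = sorted(range(len(confidences)), key=lambda i: (-confidences[i], i))
    iou_m = _box_iou_matrix(boxes)
    keep: list[int] = []
    for i in order:
        if all(iou_m[i, j] <= iou_threshold for j in keep):
            keep.append(i)
    return keep


def detect_nuclei(
    image: np.ndarray,
    model: DetectorModel,
    conf_threshold: float = 0.5,
    nms_iou: float = 0.45,
) -> list[Detection]:
    """Run the detector on an RGB float image and return suppressed detections."""
    if model is None:
        raise ValueError("no trained detector model provided")
    if not (0.0 <= conf_threshold <= 1.0 and 0.0 <= nms_iou <= 1.0):
        raise ValueError("conf_threshold and nms_iou must be in [0, 1]")
    h, w = image.shape[:2]
    boxed, scale, pad_x, pad_y = letterbox(image, model.config.input_size)
    x = boxed.transpose(2, 0, 1)[None].astype(np.float32)
    raw = model.forward(x, train=False)
    boxes, conf = decode_outputs(raw, model.config)
    sel = conf >= conf_threshold
    boxes, conf = boxes[sel], conf[sel]
    if len(boxes) == 0:
        return []
    keep = nms(boxes, conf, nms_iou)
    detections = []
    for i in keep:
        x1 = (boxes[i, 0] - pad_x) / scale
        y1 = (boxes[i, 1] - pad_y) / scale
        x2 = (boxes[i, 2] - pad_x) / scale
        y2 = (boxes[i, 3] - pad_y) / scale
        x1, x2 = np.clip([x1, x2], 0, w)
        y1, y2 = np.clip([y1, y2], 0, h)
        if x2 - x1 < 1 or y2 - y1 < 1:
            continue
        detections.append(
            Detection(box=BoundingBox(x1, y1, x2, y2), confidence=float(min(conf[i], 1.0)))
        )
    return detections


# ---------------------------------------------------------------------------
# training

def _build_targets(
    boxes: list[BoundingBox], config: DetectorConfig, grids: list[tuple[int, int]]
):
    """Assign each ground-truth box to its best-shape-IoU free anchor cell.

    Returns, per scale, a list of (anchor_idx, gy, gx, target corners).
    """
    flat_anchors = [a for scale in config.anchors_per_scale() for a in scale]
    scale_of = [i // 3 for i in range(9)]
    anchor_in_scale = [i % 3 for i in range(9)]
    per_scale: list[list] = [[], [], []]
    occupied: set[tuple[int, int, int, int]] = set()
    for b in boxes:
        wh = np.array([[b.width, b.height]])
        ious = _wh_iou(wh, np.array(flat_anchors))[0]
        for k in np.argsort(-ious):
            s = scale_of[k]
            stride = STRIDES[s]
            cx, cy = b.center
            gx = min(int(cx / stride), grids[s][1] - 1)
            gy = min(int(cy / stride), grids[s][0] - 1)
            key = (s, anchor_in_scale[k], gy, gx)
            if key not in occupied:
                occupied.add(key)
                per_scale[s].append((anchor_in_scale[k], gy, gx, b.as_tuple()))
                break
    return per_scale


def _giou_and_corner_grads(p: np.ndarray, t: np.ndarray):
    """Vectorized GIoU of pred vs target corner arrays (n,4) and d(GIoU)/d(pred)."""
    px1, py1, px2, py2 = (p[:, i] for i in range(4))
    tx1, ty1, tx2, ty2 = (t[:, i] for i in range(4))
    iw = np.minimum(px2, tx2) - np.maximum(px1, tx1)
    ih = np.minimum(py2, ty2) - np.maximum(py1, ty1)
    has_i = (iw > 0) & (ih > 0)
    iwc, ihc = np.clip(iw, 0, None), np.clip(ih, 0, None)
    inter = iwc * ihc
    ap = (px2 - px1) * (py2 - py1)
    at = (tx2 - tx1) * (ty2 - ty1)
    union = ap + at - inter
    cx1, cy1 = np.minimum(px1, tx1), np.minimum(py1, ty1)
    cx2, cy2 = np.maximum(px2, tx2), np.maximum(py2, ty2)
    ac = (cx2 - cx1) * (cy2 - cy1)
    giou = inter / union - (ac - union) / ac

    dI = np.stack(
        [
            np.where(has_i & (px1 > tx1), -ihc, 0.0),
            np.where(has_i & (py1 > ty1), -iwc, 0.0),
            np.where(has_i & (px2 < tx2), ihc, 0.0),
            np.where(has_i & (py2 < ty2), iwc, 0.0),
        ],
        axis=1,
    )
    dAp = np.stack([-(py2 - py1), -(px2 - px1), (py2 - py1), (px2 - px1)], axis=1)
    dAc = np.stack(
        [
            np.where(px1 < tx1, -(cy2 - cy1), 0.0),
            np.where(py1 < ty1, -(cx2 - cx1), 0.0),
            np.where(px2 > tx2, (cy2 - cy1), 0.0),
            np.where(py2 > ty2, (cx2 - cx1), 0.0),
        ],
        axis=1,
    )
    dU = dAp - dI
    inter_, union_, ac_ = inter[:, None], union[:, None], ac[:, None]
    dgiou = (dI * union_ - inter_ * dU) / union_**2 + (dU * ac_ - union_ * dAc) / ac_**2
    return giou, dgiou


def detector_loss_and_grads(
    raw_maps: list[np.ndarray],
    targets_per_image: list[list[list]],
    config: DetectorConfig,
    weights: LossWeights,
):
    """Composite detector loss over a batch plus d(loss)/d(raw head maps).

    Semantics match :func:`her2fish.metrics.detector_loss`: mean (1 - GIoU)
    over positive anchors, positive-weighted mean objectness BCE over all
    anchors, mean single-class BCE over positives.
    """
    batch = raw_maps[0].shape[0]
    n_anchors_total = sum(3 * m.shape[2] * m.shape[3] for m in raw_maps) * batch
    n_pos = sum(len(ts) for image_ts in targets_per_image for ts in image_ts)
    grads = [np.zeros_like(m) for m in raw_maps]
    anchors_per_scale = config.anchors_per_scale()

    loss_obj = 0.0
    loss_box = 0.0
    loss_cls = 0.0
    for s, raw in enumerate(raw_maps):
        _, ch, hh, ww = raw.shape
        nc = ch // 3
        v = raw.reshape(batch, 3, nc, hh, ww).astype(np.float64)
        grad_v = grads[s].reshape(batch, 3, nc, hh, ww)
        stride = STRIDES[s]

        # objectness BCE over every anchor (positives up-weighted)
        obj_logit = v[:, :, 4]
        t_obj = np.zeros_like(obj_logit)
        pos_idx = []  # (b, ai, gy, gx, corners)
        for b in range(batch):
            for ai, gy, gx, corners in targets_per_image[b][s]:
                t_obj[b, ai, gy, gx] = 1.0
                pos_idx.append((b, ai, gy, gx, corners))
        wgt = np.where(t_obj > 0.5, weights.obj_pos_weight, 1.0)
        loss_obj += float(
            np.sum(wgt * (np.logaddexp(0.0, obj_logit) - t_obj * obj_logit))
        )
        grad_v[:, :, 4] += (
            weights.objectness * wgt * (_sigmoid(obj_logit) - t_obj) / n_anchors_total
        )

        if not pos_idx:
            continue
        bb = np.array([i[0] for i in pos_idx])
        aa = np.array([i[1] for i in pos_idx])
        yy = np.array([i[2] for i in pos_idx])
        xx = np.array([i[3] for i in pos_idx])
        t_corners = np.array([i[4] for i in pos_idx], dtype=float)

        tx, ty = v[bb, aa, 0, yy, xx], v[bb, aa, 1, yy, xx]
        tw, th = v[bb, aa, 2, yy, xx], v[bb, aa, 3, yy, xx]
        sx, sy = _sigmoid(tx), _sigmoid(ty)
        twc, thc = np.clip(tw, -8, 8), np.clip(th, -8, 8)
        aw = np.array([anchors_per_scale[s][a][0] for a in aa])
        ah = np.array([anchors_per_scale[s][a][1] for a in aa])
        bxc = (xx + sx) * stride
        byc = (yy + sy) * stride
        bw = aw * np.exp(twc)
        bh = ah * np.exp(thc)
        p_corners = np.stack(
            [bxc - bw / 2, byc - bh / 2, bxc + bw / 2, byc + bh / 2], axis=1
        )
        giou, dgiou = _giou_and_corner_grads(p_corners, t_corners)
        loss_box += float(np.sum(1.0 - giou))
        # chain rule corner -> raw offsets; scaled by -w_giou / n_pos
        coef = -weights.giou / n_pos
        d_bx = dgiou[:, 0] + dgiou[:, 2]
        d_by = dgiou[:, 1] + dgiou[:, 3]
        d_bw = (-dgiou[:, 0] + dgiou[:, 2]) / 2
        d_bh = (-dgiou[:, 1] + dgiou[:, 3]) / 2
        clip_w = ((tw > -8) & (tw < 8)).astype(float)
        clip_h = ((th > -8) & (th < 8)).astype(float)
        np.add.at(grad_v, (bb, aa, 0, yy, xx), coef * d_bx * stride * sx * (1 - sx))
        np.add.at(grad_v, (bb, aa, 1, yy, xx), coef * d_by * stride * sy * (1 - sy))
        np.add.at(grad_v, (bb, aa, 2, yy, xx), coef * d_bw * bw * clip_w)
        np.add.at(grad_v, (bb, aa, 3, yy, xx), coef * d_bh * bh * clip_h)

        # single-class classification BCE on positives (target = 1)
        tc = v[bb, aa, 5, yy, xx]
        loss_cls += float(np.sum(np.logaddexp(0.0, tc) - tc))
        np.add.at(
            grad_v, (bb, aa, 5, yy, xx), weights.classification * (_sigmoid(tc) - 1.0) / n_pos
        )

    loss = weights.objectness * loss_obj / max(n_anchors_total, 1)
    if n_pos:
        loss += weights.giou * loss_box / n_pos + weights.classification * loss_cls / n_pos
    grads = [g.astype(np.float32) for g in grads]
    return loss, grads


# ---------------------------------------------------------------------------
# augmentation

def flip_horizontal(image: np.ndarray, boxes: list[BoundingBox]):
    w = image.shape[1]
    return image[:, ::-1], [BoundingBox(w - b.x_max, b.y_min, w - b.x_min, b.y_max) for b in boxes]


def flip_vertical(image: np.ndarray, boxes: list[BoundingBox]):
    h = image.shape[0]
    return image[::-1], [BoundingBox(b.x_min, h - b.y_max, b.x_max, h - b.y_min) for b in boxes]


def rotate90(image: np.ndarray, boxes: list[BoundingBox], k: int = 1):
    """Rotate a square image by k * 90 degrees with consistent box transform."""
    k = k % 4
    for _ in range(k):
        h = image.shape[0]
        image = np.ascontiguousarray(np.rot90(image))
        # np.rot90: out[i, j] = in[j, n-1-i]  =>  (x, y) -> (y, n-1-x)
        boxes = [BoundingBox(b.y_min, h - b.x_max, b.y_max, h - b.x_min) for b in boxes]
    return image, boxes


def translate(image: np.ndarray, boxes: list[BoundingBox], dx: int, dy: int):
    """Integer shift with zero fill; boxes clipped, dropped if centre leaves."""
    h, w = image.shape[:2]
    out = np.zeros_like(image)
    src_x = slice(max(0, -dx), min(w, w - dx))
    src_y = slice(max(0, -dy), min(h, h - dy))
    dst_x = slice(max(0, dx), min(w, w + dx))
    dst_y = slice(max(0, dy), min(h, h + dy))
    out[dst_y, dst_x] = image[src_y, src_x]
    new_boxes = []
    for b in boxes:
        cx, cy = b.center
        if not (0 <= cx + dx < w and 0 <= cy + dy < h):
            continue
        x1, x2 = np.clip([b.x_min + dx, b.x_max + dx], 0, w)
        y1, y2 = np.clip([b.y_min + dy, b.y_max + dy], 0, h)
        if x2 - x1 >= 2 and y2 - y1 >= 2:
            new_boxes.append(BoundingBox(x1, y1, x2, y2))
    return out, new_boxes


def augment_sample(image: np.ndarray, boxes: list[BoundingBox], rng: np.random.Generator):
    """Random label-consistent flip / 90-degree rotation / small translation."""
    if rng.random() < 0.5:
        image, boxes = flip_horizontal(image, boxes)
    if rng.random() < 0.5:
        image, boxes = flip_vertical(image, boxes)
    k = int(rng.integers(0, 4))
    if k and image.shape[0] == image.shape[1]:
        image, boxes = rotate90(image, boxes, k)
    dx, dy = int(rng.integers(-10, 11)), int(rng.integers(-10, 11))
    if dx or dy:
        image, boxes = translate(image, boxes, dx, dy)
    return np.ascontiguousarray(image), boxes


# ---------------------------------------------------------------------------
# training loop

def _load_split(manifest_path, input_size: int):
    from ..manifest import read_manifest
    from ..simgen import load_image

    entries = read_manifest(manifest_path)
    images, boxes, ids = [], [], []
    for e in entries:
        img = load_image(e.resolved_path)
        boxed, scale, pad_x, pad_y = letterbox(img, input_size)
        images.append(boxed.astype(np.float32))
        boxes.append(
            [
                BoundingBox(
                    a.box.x_min * scale + pad_x,
                    a.box.y_min * scale + pad_y,
                    a.box.x_max * scale + pad_x,
                    a.box.y_max * scale + pad_y,
                )
                for a in e.annotations
            ]
        )
        ids.append(e.id)
    return images, boxes, ids


def _validation_map(model, val_images, val_boxes, conf_threshold: float) -> float:
    dets = [
        detect_nuclei(img, model, conf_threshold=conf_threshold, nms_iou=0.45)
        for img in val_images
    ]
    return pooled_detection_ap(dets, val_boxes, iou_threshold=0.5)


def train_detector(
    train_manifest, val_manifest, config: TrainConfig
) -> tuple[DetectorModel, list[dict]]:
    """Train the nucleus detector; returns the best-validation-mAP checkpoint.

    Optimizes the composite GIoU + objectness + classification loss with
    Adam at the configured (fixed) learning rate; per-epoch mean training
    loss and validation mAP@0.5 are logged; the weights achieving the best
    validation mAP are restored before returning.  Reproducible given
    ``config.seed``.
    """
    tr_images, tr_boxes, tr_ids = _load_split(train_manifest, config.input_size)
    val_images, val_boxes, val_ids = _load_split(val_manifest, config.input_size)
    if not tr_images or not val_images:
        raise ValueError("empty training or validation manifest")
    overlap = set(tr_ids) & set(val_ids)
    if overlap:
        raise ValueError(f"train/val splits are not disjoint: {sorted(overlap)[:5]}")

    anchors = config.anchors or cluster_anchor_boxes(
        [b for bs in tr_boxes for b in bs], k=9
    )
    model = DetectorModel(
        DetectorConfig(input_size=config.input_size, anchors=list(anchors), seed=config.seed)
    )
    if config.pretrained_weights:
        model = DetectorModel.load(config.pretrained_weights)

    opt = nn.Adam(model.params(), lr=config.learning_rate)
    rng = np.random.default_rng(config.seed)
    grids = [
        (config.input_size // s, config.input_size // s) for s in STRIDES
    ]
    log: list[dict] = []
    best_state, best_map = None, -1.0
    for epoch in range(1, config.epochs + 1):
        perm = rng.permutation(len(tr_images))
        losses = []
        for start in range(0, len(perm), config.batch_size):
            idx = perm[start : start + config.batch_size]
            batch_imgs, batch_targets = [], []
            for i in idx:
                img, boxes = tr_images[i], tr_boxes[i]
                if config.augment:
                    img, boxes = augment_sample(img, boxes, rng)
                batch_imgs.append(img.transpose(2, 0, 1))
                batch_targets.append(_build_targets(boxes, model.config, grids))
            x = np.stack(batch_imgs).astype(np.float32)
            raw = model.forward(x, train=True)
            loss, grads = detector_loss_and_grads(
                raw, batch_targets, model.config, config.loss_weights
            )
            opt.zero_grad()
            model.backward(grads)
            opt.step()
            losses.append(loss)
        val_map = _validation_map(model, val_images, val_boxes, config.eval_conf_threshold)
        log.append(
            {"epoch": epoch, "train_loss": float(np.mean(losses)), "val_map": float(val_map)}
        )
        if val_map > best_map:
            best_map = val_map
            best_state = nn.get_state(_ParamsView(model))
    if best_state is not None:
        nn.set_state(_ParamsView(model), best_state)
    return model, log


class _ParamsView:
    """Adapter exposing a DetectorModel's params through the Layer interface."""

    def __init__(self, model: DetectorModel):
        self._model = model

    def params(self) -> list[nn.Param]:
        return self._model.params()


def write_training_log(path, log: list[dict]) -> None:
    """Write the per-epoch log as CSV (epoch, train loss, validation metric)."""
    if not log:
        raise ValueError("empty training log")
    cols = list(log[0].keys())
    with open(path, "w") as fh:
        fh.write(",".join(cols) + "\n")
        for row in log:
            fh.write(",".join(str(row[c]) for c in cols) + "\n")
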