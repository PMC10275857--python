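"""Anchor clustering, decoding/NMS, loss gradients, augmentation, training contract."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from her2fish.core import BoundingBox
from her2fish.metrics import LossWeights, detector_loss
from her2fish.models.detector import (
    DetectorConfig,
    DetectorModel,
    _build_targets,
    _sigmoid,
    augment_sample,
    cluster_anchor_boxes,
    decode_outputs,
    detect_nuclei,
    detector_loss_and_grads,
    letterbox,
    nms,
    rotate90,
    train_detector,
    translate,
)
from her2fish.models.types import TrainConfig
from her2fish.simgen import make_dataset, render_fish_image, spec_for_group

ANCHORS9 = [
    (100.0, 100.0), (80.0, 90.0), (70.0, 60.0),
    (50.0, 55.0), (40.0, 40.0), (30.0, 35.0),
    (25.0, 20.0), (15.0, 18.0), (10.0, 10.0),
]


class TestAnchorClustering:
    def test_identical_boxes_fixed_point(self):
        boxes = [BoundingBox(0, 0, 40, 40)] * 5
        anchors = cluster_anchor_boxes(boxes, k=1)
        assert anchors == [(40.0, 40.0)]

    def test_two_well_separated_clusters(self):
        boxes = [BoundingBox(0, 0, 20, 20)] * 50 + [BoundingBox(0, 0, 60, 60)] * 50
        anchors = sorted(cluster_anchor_boxes(boxes, k=2))
        assert anchors[0] == pytest.approx((20.0, 20.0))
        assert anchors[1] == pytest.approx((60.0, 60.0))

    def test_k9_on_synthetic_boxes_sorted_into_scales(self, small_spec):
        boxes = []
        for seed in range(12):
            _, anns = render_fish_image(small_spec, seed=seed)
            boxes += [a.box for a in anns]
        anchors = cluster_anchor_boxes(boxes, k=9)
        areas = [w * h for w, h in anchors]
        assert areas == sorted(areas, reverse=True)  # non-increasing
        per_scale = DetectorConfig(anchors=anchors).anchors_per_scale()
        assert [len(s) for s in per_scale] == [3, 3, 3]

    def test_too_few_boxes(self):
        with pytest.raises(ValueError):
            cluster_anchor_boxes([BoundingBox(0, 0, 1, 1)], k=9)


class TestLetterboxAndCrops:
    def test_identity_when_already_square(self):
        img = np.random.default_rng(0).uniform(size=(64, 64, 3))
        out, scale, px, py = letterbox(img, 64)
        assert out is img and scale == 1.0 and px == py == 0.0

    def test_aspect_preserving_pad(self):
        img = np.ones((50, 100, 3))
        out, scale, px, py = letterbox(img, 64)
        assert out.shape == (64, 64, 3)
        assert scale == pytest.approx(0.64)
        assert py == (64 - 32) // 2 and px == 0


class TestDecodeAndNms:
    def test_nms_suppresses_duplicates(self):
        boxes = np.array([[0, 0, 10, 10], [0, 0, 10, 10], [30, 30, 40, 40]], dtype=float)
        conf = np.array([0.9, 0.8, 0.7])
        assert nms(boxes, conf, 0.45) == [0, 2]

    def test_decode_shapes_and_ranges(self):
        cfg = DetectorConfig(input_size=64, anchors=ANCHORS9)
        model = DetectorModel(cfg)
        x = np.zeros((1, 3, 64, 64), dtype=np.float32)
        raw = model.forward(x)
        boxes, conf = decode_outputs(raw, cfg)
        n_anchors = 3 * (8 * 8 + 4 * 4 + 2 * 2)
        assert boxes.shape == (n_anchors, 4) and conf.shape == (n_anchors,)
        assert np.all(conf >= 0) and np.all(conf <= 1)

    def test_threshold_above_every_confidence_gives_empty(self):
        model = DetectorModel(DetectorConfig(input_size=64, anchors=ANCHORS9))
        img = np.zeros((64, 64, 3))
        assert detect_nuclei(img, model, conf_threshold=1.0) == []

    def test_missing_model_rejected(self):
        with pytest.raises(ValueError):
            detect_nuclei(np.zeros((8, 8, 3)), None)


class TestDetectorLossGradients:
    def test_analytic_gradients_match_finite_differences(self):
        rng = np.random.default_rng(1)
        cfg = DetectorConfig(input_size=64, anchors=ANCHORS9)
        grids = [(8, 8), (4, 4), (2, 2)]
        raw = [rng.normal(0, 1, (1, 18, g, g)) for g in (8, 4, 2)]
        boxes = [BoundingBox(10, 12, 40, 43), BoundingBox(30, 5, 55, 30)]
        targets = [_build_targets(boxes, cfg, grids)]
        w = LossWeights(obj_pos_weight=4.0)
        loss, grads = detector_loss_and_grads(raw, targets, cfg, w)
        assert np.isfinite(loss)
        eps = 1e-5
        for s in range(3):
            flat = raw[s]
            picks = rng.choice(flat.size, 25, replace=False)
            for lin in picks:
                i = np.unravel_index(lin, flat.shape)
                old = flat[i]
                flat[i] = old + eps
                lp, _ = detector_loss_and_grads(raw, targets, cfg, w)
                flat[i] = old - eps
                lm, _ = detector_loss_and_grads(raw, targets, cfg, w)
                flat[i] = old
                numeric = (lp - lm) / (2 * eps)
                assert grads[s][i] == pytest.approx(numeric, abs=1e-6, rel=1e-4)

    def test_training_loss_agrees_with_reference_definition(self):
        """The vectorized training loss equals the metrics-module composite loss."""
        rng = np.random.default_rng(5)
        cfg = DetectorConfig(input_size=64, anchors=ANCHORS9)
        grids = [(8, 8), (4, 4), (2, 2)]
        raw = [rng.normal(0, 0.5, (1, 18, g, g)) for g in (8, 4, 2)]
        gt = [BoundingBox(8, 8, 45, 40)]
        targets = [_build_targets(gt, cfg, grids)]
        weights = LossWeights(obj_pos_weight=3.0)
        loss, _ = detector_loss_and_grads(raw, targets, cfg, weights)

        # reconstruct the reference inputs: decoded boxes and probabilities
        pred_boxes, target_boxes, pred_cls = [], [], []
        obj_probs, obj_targets = [], []
        anchors_per_scale = cfg.anchors_per_scale()
        for s, g in enumerate(grids):
            v = raw[s].reshape(3, 6, g[0], g[1])
            obj = _sigmoid(v[:, 4]).ravel()
            t_obj = np.zeros_like(obj)
            for ai, gy, gx, corners in targets[0][s]:
                t_obj[np.ravel_multi_index((ai, gy, gx), (3, g[0], g[1]))] = 1.0
                stride = (8, 16, 32)[s]
                aw, ah = anchors_per_scale[s][ai]
                bx = (gx + _sigmoid(v[ai, 0, gy, gx])) * stride
                by = (gy + _sigmoid(v[ai, 1, gy, gx])) * stride
                bw = aw * np.exp(np.clip(v[ai, 2, gy, gx], -8, 8))
                bh = ah * np.exp(np.clip(v[ai, 3, gy, gx], -8, 8))
                pred_boxes.append(
                    BoundingBox(bx - bw / 2, by - bh / 2, bx + bw / 2, by + bh / 2)
                )
                target_boxes.append(BoundingBox(*corners))
                pred_cls.append(_sigmoid(v[ai, 5, gy, gx]))
            obj_probs.append(obj)
            obj_targets.append(t_obj)
        reference = detector_loss(
            pred_boxes,
            target_boxes,
            np.concatenate(obj_probs),
            np.concatenate(obj_targets),
            pred_class=np.array(pred_cls),
            weights=weights,
        )
        assert loss == pytest.approx(reference, rel=1e-9)


class TestAugmentation:
    @staticmethod
    def _planted(h=32, w=32, box=(8, 10, 14, 18)):
        img = np.zeros((h, w, 3))
        b = BoundingBox(*box)
        cx, cy = int(b.center[0]), int(b.center[1])
        img[cy, cx, 0] = 1.0
        return img, b

    @pytest.mark.parametrize("k", [1, 2, 3])
    def test_rotation_overlay_consistency(self, k):
        """A pixel planted at the box centre stays inside the transformed box."""
        img, b = self._planted()
        out, boxes = rotate90(img, [b], k)
        (nb,) = boxes
        ys, xs = np.nonzero(out[:, :, 0])
        assert nb.x_min <= xs[0] + 0.5 <= nb.x_max
        assert nb.y_min <= ys[0] + 0.5 <= nb.y_max

    def test_translation_overlay_and_dropping(self):
        img, b = self._planted()
        out, boxes = translate(img, [b], dx=5, dy=-3)
        (nb,) = boxes
        ys, xs = np.nonzero(out[:, :, 0])
        assert nb.x_min <= xs[0] + 0.5 <= nb.x_max
        assert nb.y_min <= ys[0] + 0.5 <= nb.y_max
        # shifting the box fully outside drops it
        _, gone = translate(img, [b], dx=31, dy=0)
        assert gone == []

    def test_random_augment_keeps_boxes_in_bounds(self):
        rng = np.random.default_rng(0)
        img, b = self._planted()
        for _ in range(25):
            out, boxes = augment_sample(img, [b], rng)
            for nb in boxes:
                assert 0 <= nb.x_min < nb.x_max <= 32
                assert 0 <= nb.y_min < nb.y_max <= 32


@pytest.fixture(scope="module")
def tiny_dataset(tmp_path_factory):
    spec = spec_for_group(5, dataclasses.replace(
        spec_for_group(5),
        image_size=(96, 96), n_nuclei=(2, 3), nucleus_radius=(10, 14),
        her2_spot_radius=(1.5, 2.0), cep17_spot_radius=(1.5, 2.0),
    ))
    out = tmp_path_factory.mktemp("tinyds")
    return make_dataset(spec, 8, (0.5, 0.25, 0.25), seed=3, out_dir=out)


class TestTrainingContract:
    def test_one_epoch_logs_finite_loss(self, tiny_dataset):
        cfg = TrainConfig(epochs=1, batch_size=2, input_size=96, seed=0, augment=False)
        model, log = train_detector(tiny_dataset["train"], tiny_dataset["val"], cfg)
        assert len(log) == 1
        assert np.isfinite(log[0]["train_loss"])
        assert 0.0 <= log[0]["val_map"] <= 1.0

    def test_same_seed_reproduces_loss_sequence(self, tiny_dataset):
        cfg = TrainConfig(epochs=2, batch_size=2, input_size=96, seed=1)
        _, log1 = train_detector(tiny_dataset["train"], tiny_dataset["val"], cfg)
        _, log2 = train_detector(tiny_dataset["train"], tiny_dataset["val"], cfg)
        assert [r["train_loss"] for r in log1] == [r["train_loss"] for r in log2]

    def test_non_disjoint_splits_rejected(self, tiny_dataset):
        cfg = TrainConfig(epochs=1, batch_size=2, input_size=96)
        with pytest.raises(ValueError, match="disjoint"):
            train_detector(tiny_dataset["train"], tiny_dataset["train"], cfg)

    def test_checkpoint_round_trip(self, tiny_dataset, tmp_path):
        cfg = TrainConfig(epochs=1, batch_size=2, input_size=96, seed=0)
        model, _ = train_detector(tiny_dataset["train"], tiny_dataset["val"], cfg)
        path = tmp_path / "det.npz"
        model.save(path)
        loaded = DetectorModel.load(path)
        x = np.random.default_rng(0).uniform(size=(1, 3, 96, 96)).astype(np.float32)
        for a, b in zip(model.forward(x), loaded.forward(x)):
            assert np.array_equal(a, b)
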