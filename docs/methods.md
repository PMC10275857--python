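# Methods

## The reading being automated

A dual-probe HER2 FISH image shows, per tumour-cell nucleus, punctate HER2
signals (red channel here; SpectrumOrange in the PathVysion assay) and
CEP17 centromere signals (green) over a DAPI nuclear counterstain (blue).
The image-level readout is

- average HER2 copy number `avg = total HER2 signals / n nuclei`,
- HER2/CEP17 ratio `R = total HER2 / total CEP17` (identically the ratio of
  the two averages),

classified into the five 2018 ASCO/CAP groups (see README table). All
guideline thresholds (2.0, 4.0, 6.0) are inclusive on the `>=` side.
Classification always uses unrounded values; two-decimal
(round-half-to-even) rounding is display-only. An erratum note: the source
description of this workflow states both formulas in inverted form
(nuclei/signals, CEP17/HER2); its own worked numbers (13.80 copies,
13.80/2.60 = 5.31) fix the direction implemented here.

Degenerate images are first-class outcomes: zero detected nuclei yields a
`no_nuclei` status and zero counted CEP17 signals a `no_cep17` status,
never a silent group. Regressed (non-integer) counts are summed unrounded;
annotation files require integers.

## Two-stage pipeline

**Stage 1 — nucleus detection.** An anchor-based single-class detector in
the YOLO family: a strided convolutional backbone with heads at strides
8/16/32, three anchors per scale from IoU k-means over the training boxes
(k = 9, deterministic quantile initialization, anchors sorted by
non-increasing area, largest anchors on the coarsest scale). Offsets decode
as `b_xy = (cell + sigmoid(t_xy)) * stride`, `b_wh = anchor * exp(t_wh)`
(exponent clipped to ±8); confidence is `sigmoid(obj) * sigmoid(cls)`;
greedy NMS follows. The training loss is the composite
`(1 − GIoU)` over positive anchors + objectness binary cross-entropy over
all anchors + single-class classification cross-entropy over positives.
Each ground-truth box is assigned to its best shape-IoU anchor at the cell
containing the box centre (next-best anchor if occupied). The three loss
terms are weighted 1.0 each; inside the objectness term positive anchors
carry weight `obj_pos_weight` (training default 100), without which the
~1500:5 background:foreground anchor imbalance drives objectness to zero
before localization can be learned.

**Stage 2 — signal counting.** Each detected box, expanded by a 15% pad and
edge-clamped, is cropped and resized to 80×80, and a small convolutional
regressor (stride-1 stem so 1–2-px spots survive the first layer; strided
stack; global average pool; 2-output linear head) predicts the (HER2,
CEP17) counts, clamped at zero. Targets are standardized per channel
(mean/std fitted on the training counts and stored in the checkpoint):
HER2 counts span roughly 7× the CEP17 range, and without standardization
the regressor spends its 10-epoch budget on the HER2 scale alone. The 80-px
patch (rather than 64) keeps ~2 samples per spot sigma after resize, which
measurably improves count error at the same epoch budget.

Both models train with Adam at a fixed learning rate of 1e-3 (no decay),
batch shuffling, and label-consistent augmentation (horizontal/vertical
flips, 90° rotations, integer translations up to 10 px with box clipping
and centre-out dropping). Model selection is by best validation mAP@0.5
(detector) and best validation MSE (counter); per-epoch logs are returned
and writable as CSV. All randomness flows from a single integer seed; runs
are bit-reproducible. Initialization is random by default; a
`pretrained_weights` hook loads an external checkpoint where one exists.
Gradients are hand-derived (the network core is plain numpy); the GIoU
gradient is analytic in the box corners with subgradients at ties, and is
finite-difference-checked in the test suite.

**Classical backends.** Each stage also has a deterministic
image-processing backend, used both as a practical baseline and as an
exact oracle on clean synthetic fields:

- detection: threshold the blue channel (default 0.15), label connected
  components, filter by area (default ≥ 50 px²), confidence 1.0;
- counting: per channel, count local maxima at least `min_separation`
  (default 2 px) apart and above `max(0.2, 0.5 × channel max)`; a channel
  whose maximum is below the absolute floor 0.2 counts zero. Maxima are
  plateau regions, labelled with 8-connectivity, so a saturated fused
  cluster — or the few-pixel tie plateau that 8-bit image quantization
  makes of a single Gaussian peak — counts once.

Classical counting crops the detected box with **no** pad at native
resolution; the generator's clearance geometry (below) then guarantees no
neighbouring nucleus's signal contributes a countable maximum.

## Synthetic data generator

`simgen` renders what the pipeline consumes: dark background, soft-edged
elliptical blue nuclei (semi-axes sampled per nucleus, random orientation),
isotropic Gaussian spots (sigma = radius/2, truncated at 3 sigma) placed
inside each nucleus, additive Gaussian background noise (default sigma
0.02), clipped to [0,1], written as lossless PNG (JPEG quality 95
optionally, matching how clinical scanners store fields). Ground truth is
exact: each nucleus's axis-aligned ellipse bounding box with the planted
integer counts; the manifest also records the group derived from the
planted counts.

Defaults describe the clinical regime: 512×512 fields, 5–25 nuclei of
radius 20–40 px, 1–30 HER2 and 1–6 CEP17 spots per nucleus of radius 2–4 px
and peak 0.7–1.0, nucleus intensity 0.35–0.6. Resolution/magnification of
the source material is unreported, so pixel sizes are free parameters, not
claims.

Resolvability is engineered, since the classical counter must be an exact
oracle on clean fields:

- per-nucleus counts are sampled *first* and the nucleus radius floor is
  derived from spot-packing capacity (each spot claims a disc of half its
  minimum resolvable distance; packing safety factor 2.5);
- spot centres stay within 0.7 of the nucleus radius and keep centre
  distance ≥ max(4 px, 1.25·(r_i + r_j));
- nucleus centres keep distance ≥ 1.3·(R_1 + R_2), scaled down by the
  allowed overlap fraction.

Together these bounds keep every planted spot a distinct maximum of its own
box and keep neighbours' Gaussian tails below the counting threshold inside
any box. When a sampled field saturates (no position satisfies the
clearance after bounded retries), generation stops at the placed nuclei
provided the minimum of the `n_nuclei` range was reached, else raises — a
saturated field is a normal crowded specimen, an unplaceable minimum is an
error. Artefact flags reproduce documented clinical failure modes:
`her2_clustering` fuses the HER2 spots into ≤ 3 tight blobs (ground truth
keeps the planted count, so regression-style counting must undercount),
`weak_cep17` scales green peaks to 25% (dropping many below the counter's
absolute floor), `coarse_cep17` doubles green spot radii, and
`nucleus_overlap` relaxes the clearance so nuclei overlap and merge under
component labelling.

What the generator does *not* emulate: tissue texture and autofluorescence,
optical PSF/z-stack effects, chromatic aberration, staining gradients, and
truncated nuclei at section boundaries. Passing tests therefore demonstrate
the correctness of the pipeline's mechanics and its directional behaviour
under the modelled artefacts — not clinical-grade accuracy on real
material.

## Evaluation

Detection quality is average precision over the all-point precision
envelope (not 11-point interpolation; deterministic and standard in current
practice), with greedy confidence-ordered matching, each ground truth
consumed once, ties in confidence broken by input index. The matching IoU
threshold defaults to 0.5 (reported as mAP@0.5) and is configurable; the
threshold and interpolation behind previously reported mAP values for this
workflow are unstated, so no numeric mAP value is treated as reproducible.
Dataset-level mAP pools per-image matches under a global confidence
ranking. With one foreground class, mAP equals AP.

Classification quality is the 5×5 confusion matrix (rows = reference,
columns = predicted), overall accuracy = trace/total and per-reference-row
accuracy. Failure-status images count against the accuracy denominators
but cannot enter the matrix; the report carries their count separately.

Dataset splits use largest-remainder apportionment, which reproduces the
published 551/183/184 partition of 918 images at the published fractions;
every image belongs to exactly one split.

## Desk-scale study conditions

The learned pipeline is exercised end-to-end at a reduced scale chosen to
match the synthetic regime rather than the clinical one: 240 fields of
160×160 px (180 train / 30 val / 30 test), 3–6 nuclei of radius 14–22 px,
spot radius 1.5–2.5 px, one spec per ASCO/CAP group cycled round-robin;
detector 10 epochs / batch 8 at native 160 resolution, counter 10 epochs /
batch 4 on 80-px patches; all seeds fixed. Inference uses confidence 0.5
and NMS IoU 0.25 for this regime — synthetic nuclei are non-overlapping by
construction, so duplicate suppression can be stricter than the clinical
default (0.45) without merging true neighbours. Under these conditions the
run reaches mAP@0.5 ≈ 0.99 and ≈ 93% held-out group accuracy; the test
suite asserts the deliberately loose regression floors mAP ≥ 0.5 and
accuracy ≥ 80%, which hold across retrains with margin. Per-image (not
per-case) classification is primary; an optional reducer pools a case's
per-nucleus counts across images before summarizing.

## Numerical and design choices

- Boxes are 0-based, half-open pixel rectangles; degenerate boxes are
  unconstructible.
- GIoU = IoU − |C \ (A∪B)|/|C| with C the smallest enclosing box; range
  (−1, 1], equal to IoU when C equals the union. Verified against a
  pixel-rasterization oracle.
- BCE probabilities are clipped at 1e-12 before logs; the loss of a perfect
  prediction is 0 to machine precision.
- Letterboxing preserves aspect ratio, pads with zeros, and maps boxes
  affinely in both directions.
- `exp` inputs in box decoding are clipped to ±8 (gradient masked outside),
  preventing overflow from untrained heads.
- Network arithmetic is float32; losses accumulate in float64.
- Checkpoints are `.npz` archives embedding the architecture/anchor/
  normalization config as JSON with a schema version; loading rejects
  mismatched checkpoint kinds.
- The full 53-layer feature extractor of the original detector design and
  the 18-layer residual regressor are represented by width/depth-
  configurable reduced stacks; at desk scale the small defaults train in
  minutes on one CPU, and the architecture hooks (plus
  `pretrained_weights`) are where a full-scale configuration would plug in.

## Known limitations

- The learned models are validated only on the synthetic regime; no claim
  transfers to clinical images without retraining and revalidation.
- Heavily overlapping nuclei merge into one detection under the classical
  backend (and are hard for the learned one) — the same failure mode
  reported for clinical material; heterogeneity assessment and
  pathologist-in-the-loop review are out of scope.
- The classical counter undercounts fused clusters by construction; this
  direction (never the magnitude) is asserted in tests.
- IHC scoring, reflex-testing logic and case-level reporting rules are not
  implemented.
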