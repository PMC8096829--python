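# Methods

## Problem and model

`spinemark` localizes vertebral corner landmarks in sagittal radiographs
of the thoracolumbar spine and derives three clinical angles from them.
The pipeline has two steps:

**Step I (whole image).** The radiograph is resized to a square network
input (cubic interpolation; the aspect ratio is intentionally not
preserved, and the dynamic range is untouched) and intensities are
normalized.  Two networks run on this input:

* a **presence classifier** with 24 sigmoid outputs, one per spine level
  C2..S1, trained with binary cross-entropy against the presence vector
  derived from the annotations;
* a **global corner localizer** with 24 x 4 heatmap channels (4 corners
  per level) read out by a DSNT head into a 24 x 4 x 2 matrix of
  normalized coordinates.

**Step II (single vertebra).** For every level whose presence
probability reaches the threshold (default 0.5), the tight bounding box
of its step-I corners is grown by 70% of each side length (35% margin
per side), the crop is resized to the refiner input, and a third network
with a single 1 x 4 x 2 DSNT head re-localizes the corners at the finer
effective pixel size.  The inverse crop transform — divide by the resize
scale, add the crop origin — returns the corners to original-image
pixels.  If the crop is degenerate the step-I corners are kept and the
detection is flagged `step-I-only`.

**Angles.** L1–L5 lordosis is the unsigned angle between the L1 upper
and L5 lower endplate lines; L1–S1 uses the S1 upper endplate; the
sacral slope (SS) is the angle of the S1 upper endplate to the
horizontal.  Angles are computed from direction vectors
(`atan2(|cross|, |dot|)`), which handles vertical endplates without
slope infinities, and lie in [0°, 90°].  The source material never
defines a sign convention for kyphotic configurations, and the printed
population extrema (minimum 0°, maxima below 90°) are consistent with
unsigned angles, so unsigned angles are implemented.

## DSNT head

Each heatmap channel is normalized by a spatial softmax (strictly
positive, sums to 1; softmax rather than rectification-based
normalization because it guarantees differentiability everywhere).  Cell
`i` of an `n`-cell axis sits at the normalized coordinate
`(2i + 1 - n)/n`, so pixel centers lie strictly inside (-1, 1);
`denormalize` is its exact inverse.  The predicted coordinate is the
expectation of the grid under the heatmap distribution, and training
minimizes the mean Euclidean distance between predicted and target
normalized coordinates.  No auxiliary heatmap regularizer is used.

Radiographs do not always show all 24 levels.  Absent levels (and the
two invalid S1 lower corners) are **masked out of the loss** rather than
given fabricated targets; this is the only choice that does not invent
supervision, and it is the main training-semantics decision the source
description leaves open.

## Conventions

* Pixel coordinates are 0-based, origin top-left, y down.
* Corner order is fixed: upper-anterior, upper-posterior,
  lower-anterior, lower-posterior.  A fixed order is required for the
  four heatmap channels to mean the same corner on every image.
* Horizontal flips swap anterior/posterior within each endplate so the
  channel semantics survive augmentation.
* S1 is stored with its two upper-endplate corners only
  (`valid_mask = [1,1,0,0]`); the 24 x 4 x 2 matrix still reserves four
  channels for S1 with the lower two masked everywhere.  If annotations
  arrive with four S1 corners the reader accepts and down-masks them.

## Backbones

The three networks share a compact architecture: coordinate channels
appended to the grayscale input, a stack of 3 x 3 strided convolutions
with ReLU, and a task head (global average pooling + linear for
presence; coordinate channels + a two-layer 1 x 1 convolution for the
heatmaps).  Families:

| family      | stages (channels, stride)          | heatmap stride |
|-------------|------------------------------------|----------------|
| `tiny`      | (16,2) (24,2) (32,2)               | 8              |
| `tiny-fine` | (16,2) (24,2) (32,1)               | 4              |
| `small`     | (16,2) (32,2) (48,2) (64,2)        | 16             |

Coordinate channels matter here: standing sagittal radiographs place
the sacrum low and the thoracic levels high, so absolute position is
strongly informative of level identity, and small stacks have limited
receptive fields.  Appending the coordinates again before the 1 x 1
heatmap head lets the head shape spatial logits directly from position,
which speeds up convergence of the DSNT expectation considerably.
Network inputs are standardized per image (zero mean, unit variance) to
remove exposure/collimation brightness nuisance.

ImageNet-pretrained backbones are not part of this implementation;
`pretrained=True` is rejected explicitly.  The published
standard-scale hyperparameters are kept as stage defaults (presence and
refiner: learning rate 1e-4, batch 16; global localizer: 1e-3, batch 8;
200 epochs; learning rate x0.1 after 10 epochs without validation-loss
improvement; checkpoint at the best validation loss).  "Loss did not
improve" is read as the validation loss, the same quantity monitored
for checkpointing.

## Augmentations (training only)

* **Random caudal crop**: a cut y-coordinate is rejection-sampled
  (uniform in the lower image half, at most 50 tries) and accepted when
  the most caudal fully visible vertebra becomes L5, L4 or L3 and at
  least 3 vertebrae remain.  It prevents the classifier from learning
  "the lowest visible level is the sacrum".
* Random rotations (default ±10°; samples that would push a landmark
  off-canvas are resampled with a shrunk angle) and horizontal flips
  with corner-role swap.
* Elastic deformation: Gaussian-filtered white-noise displacement field
  (amplitude `elastic_alpha` px, smoothness `elastic_sigma` px) applied
  to pixels and evaluated at each landmark; additive Gaussian intensity
  noise; intensities re-clipped to [0, 1].

Refiner training crops are built from ground-truth corners with random
box jitter (±12% shift/scale).  The jitter emulates the noise of step-I
localization at inference time; without it the refiner would only ever
see perfectly centered vertebrae and would not act as a corrector.

## Synthetic radiograph generator

No public dataset with per-corner annotations exists, so all training
and evaluation runs on simulated radiographs.  The generator renders
vertebral bodies as bright convex quadrilaterals (Gaussian-blurred)
along a smooth sagittal curve whose endplate tilts realize sampled
angle targets:

* SS ~ truncated normal, mean 35.8°, sd 14°, support [0°, 89.4°];
* L1–L5 ~ truncated normal, mean 36.3°, sd 15°, support [0.1°, 86.8°];
* L1–S1 = L1–L5 + an L5–S1 disc wedge ~ N(13.6°, 4°), clipped to
  [0.1°, 89.9°].

Means and supports match the descriptive statistics of the large
clinical lumbar population the pipeline is designed for; the standard
deviations are not printed anywhere and were chosen once (~range/6) so
the truncated distributions fill the printed supports.  The tilt profile
is anchored exactly at S1-upper, L5-lower and L1-upper, linear across
the lumbar endplates, drifting mildly kyphotic above L1; per-corner
jitter slides corners along the endplate direction only, so the stored
corners reproduce the sampled angles exactly (the regression test allows
0.5°).  Field of view varies by sampling the most cranial rendered
level (T9..L1 with lumbar-heavy census weights: 0.08/0.26/0.37/0.26/0.03);
resolution varies by a per-image canvas factor in [0.85, 1.25].
Radiograph nuisances: intensity noise, black collimation borders (kept
clear of the landmarks), global brightness extremes, and optional bright
rod-and-screw strokes posterior to the column.

What the simulator does **not** model: bone texture and trabecular
detail, soft tissue and organ shadows, fractures, spondylolisthesis,
osteophytes, projection effects and patient rotation.  Passing the
end-to-end tests therefore shows that the pipeline machinery (networks,
transforms, bookkeeping, metrics) recovers geometry under
radiograph-like nuisance, not that the tiny networks would reach
clinical accuracy on real radiographs.

## Evaluation metrics

Corner errors are absolute x/y differences normalized by the true
vertebral width/height (the x/y extents of the true corner set) in
percent.  S1 contributes only its two upper corners; because its
two-point extent has no meaningful height, S1 y-errors are normalized by
its endplate width.  Per-level summaries are sample medians (the error
distributions are non-Gaussian; a Shapiro–Wilk p-value is reported for
transparency), and the global summary is the per-level-count weighted
mean of the medians.  PCK uses strict inequality against thresholds of
5..100% of the true width in steps of 5.  Detection accuracy is the
fraction of truth vertebrae whose level appears among the detections;
spurious detections are reported separately and missed vertebrae are
excluded from the error distributions (reported as a miss list), so both
views of gross failures are preserved.  Angle agreement reports median
and maximum absolute error, the fraction of errors above 5° (the
accepted error of human observers), least-squares R², the SD of the
differences and Bland–Altman mean difference with 95% limits.

The per-level reference table shipped in
`spinemark.evaluate.REFERENCE_LEVEL_SUMMARY` reproduces the published
x-axis weighted means exactly (2.20% after step I, 1.98% after step II).
The published y-axis summary values (2.04/1.68) do **not** equal the
weighted mean of the published per-level y rows (which give 2.34/1.98);
the inconsistency is in the published table itself and is therefore
documented rather than resolved; only the x-axis summaries are used as
reference values.

## Scaled-down study conditions

The clinical study trained ImageNet backbones on 10,193 radiographs on
a GPU; its test-set numbers are not reproducible at desk scale.  The
package's end-to-end experiment (`spinemark.experiments`) uses: 200
training / 30 validation / 50 test simulated radiographs at ~112 px,
`tiny-fine` backbones (96 px step-I input, 48 px refiner input,
~40k parameters), 10 epochs per network, Adam (presence 2e-3 batch 8;
global 1e-2 batch 4; refiner 1e-2 batch 8, at most 1000 crops).  The
caudal crop augmentation is applied to presence training (where it
serves its purpose) but not to the corner localizer, whose short
schedule benefits from a stable level-position mapping.  Expected
outcomes at this scale: detection accuracy ≈ 0.94, median normalized
corner error ≈ 5% of width, and step-II refinement roughly halving the
weighted-mean medians relative to step I — mirroring the direction of
the published 2.20% → 1.98% improvement.

## Numerical choices and degenerate inputs

* "Extended the bounding box area by 70%" is read as growing each side
  length by 70% (the crop in the original figure shows generous margins
  on both axes); the literal area reading (sides x sqrt(1.7)) is noted
  as defensible, and the factor is a parameter.
* The S1 tight box can be y-degenerate (flat endplate); crop boxes floor
  each axis span at 40% of the other, grown mostly caudally in y where
  the sacral body continues.
* Expectations of normalized heatmaps cannot leave [-1, 1]^2 (convexity).
* All-masked coordinate batches define the loss as 0 with a warning.
* Constant images under min-max normalization map to zeros with a warning.
* The presence threshold (0.5) is not stated in the source description;
  no contiguity is enforced on detected levels (the original system
  demonstrably missed mid-column vertebrae, so it did not enforce
  contiguity either).
* Determinism: every random choice flows from explicit generators;
  per-image simulator seeds are spawned from the master seed.

## Known limitations

* The tiny backbones are not intended to transfer to real radiographs;
  they demonstrate the pipeline at CPU scale.
* Level identity rests on channel index plus learned position cues; a
  radiograph with an atypical field of view (e.g. mid-thoracic only)
  would defeat the tiny models.
* Pelvic incidence, pelvic tilt and sagittal vertical axis are out of
  scope.
* The DICOM reader handles single-frame grayscale files only and
  min-max rescales intensities.
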