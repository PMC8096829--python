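# spinemark

Automatic vertebra identification, corner-landmark localization and
spinopelvic angle measurement in sagittal spine radiographs.

Clinical spine assessment rests on angles — L1–L5 and L1–S1 lordosis,
sacral slope — that are still widely measured by hand from the corners
of the vertebral bodies, with well-known intra- and inter-observer
variability.  `spinemark` implements a fully automatic two-step
pipeline for radiologists and musculoskeletal researchers:

1. **Step I** — the radiograph is resized to a square input; a 24-way
   sigmoid classifier decides which levels (C2..S1) are visible, and a
   fully convolutional localizer produces 24 x 4 spatial heatmaps that a
   **differentiable spatial-to-numerical transform (DSNT)** converts to
   a 24 x 4 x 2 matrix of corner coordinates: each heatmap is softmax
   normalized and the coordinate is the expectation
   `x̂ = Σᵢⱼ p(i,j) · X(j)` over a normalized [-1, 1] grid, so the whole
   head is trained end-to-end by minimizing the Euclidean distance
   `‖p̂ - p‖` to the annotated corners.
2. **Step II** — each detected vertebra is cropped (tight corner box
   grown by 70%), resized, and a second DSNT network (1 x 4 x 2 output)
   refines the corners at a finer effective pixel size; the inverse crop
   transform maps them back to original-image pixels.

From the corners, the package computes the angle between the L1 upper
and L5 lower endplate lines (L1–L5 lordosis), between the L1 upper and
S1 upper endplates (L1–S1), and between the S1 upper endplate and the
horizontal (sacral slope, SS).

Evaluation follows the standard keypoint methodology: per-corner errors
normalized by vertebral width/height, e.g. `e(x) = |p̂(x) − p(x)| /
length(x) · 100%`, per-level medians, count-weighted mean medians, PCK
curves (thresholds 5–100% of vertebral width), detection accuracy, and
angle agreement statistics (median absolute error, R², Bland–Altman).

Because no public radiograph dataset with per-corner annotations
exists, the package ships a synthetic radiograph simulator
(`spinemark.synthetic_spine`) that renders spines with exact
ground-truth corners, angle distributions matching a large clinical
lumbar population (means 36.3°/49.9°/35.8° for L1–L5/L1–S1/SS), varying
fields of view and resolution, collimation borders, brightness extremes
and instrumentation-like artifacts.  Everything — training, inference,
evaluation — runs on a single CPU with compact convolutional backbones.

## Worked example

Simulate a small dataset, train the three networks, and measure a
radiograph:

```sh
spinemark simulate --n 280 --out data/ --fractions 0.72 0.10 0.18 --seed 1
spinemark train --stage presence --data data/ --family tiny-fine --input-size 96 --epochs 10 --out presence.npz
spinemark train --stage global   --data data/ --family tiny-fine --input-size 96 --epochs 10 --out global.npz
spinemark train --stage refine   --data data/ --family tiny-fine --input-size 48 --epochs 10 --out refine.npz
spinemark infer --image data/images/sim_00270.png \
    --presence presence.npz --corners global.npz --refiner refine.npz
```

The Python API runs the same study in one call:

```python
from spinemark.experiments import run_scaled_experiment
res = run_scaled_experiment(seed=1)
print(round(res["detection_accuracy"], 3))            # 0.945
print(round(res["median_norm_corner_error_pct"], 1))  # 4.8
print(round(res["weighted_median_x_step1"], 2),
      round(res["weighted_median_x_step2"], 2))       # 5.92 3.06
```

Reading: on 50 held-out synthetic radiographs, 94.5% of vertebrae were
detected and labeled with the correct level; the median corner error of
the full pipeline was 4.8% of the vertebral width; and step-II
refinement cut the weighted-mean median x-error from 5.92% to 3.06% —
the coarse-to-fine refinement is what buys sub-vertebra precision.

## Layout

| module | contents |
|---|---|
| `spinemark.annotations` | levels, corner sets, annotation CSV and image I/O |
| `spinemark.synthetic_spine` | radiograph simulator with exact ground truth |
| `spinemark.geometry` | crop transforms, extended boxes, endplate angles |
| `spinemark.dsnt` | heatmap normalization, soft-argmax, losses |
| `spinemark.augment` | caudal crop, rotations/flips, elastic, noise |
| `spinemark.localizer` | the three networks, training loops, inference |
| `spinemark.evaluate` | error metrics, PCK, detection accuracy, agreement |
| `spinemark.experiments` | the reproducible desk-scale study |

See `docs/methods.md` for the model, parameter choices and limitations.
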