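# celltyper

Supervised cell-type classification directly on multiplexed tissue images
(MIBI-TOF, CODEX, IMC), for labs that already have segmentation masks and a
modest set of expert-labeled cells and want the rest of their dataset labeled
consistently — with a per-cell confidence score instead of take-it-or-leave-it
cluster assignments.

## The method

Classical pipelines reduce each cell to a row of an expression matrix (per-cell
mean counts per protein) and assign types by gating or clustering.  Spillover
from densely packed neighbors, noise patches and segmentation errors corrupt
those rows in ways that are obvious in the image but invisible in the matrix.
`celltyper` therefore classifies cells *from the image*: the input for cell
*i* is a `(K+2, S, S)` tensor — crops of all K protein channels centered on the
cell, a binary mask of the cell itself, and a binary mask of every other cell
in the window.  An ensemble of independently seeded convolutional networks is
trained with cross-entropy on class-balanced draws (rare classes are upsampled
equally or by major lineage), with augmentations modelling the real nuisance
variation: dihedral transforms, shifts/resizing of the segmentation mask,
per-channel registration shifts, and Gaussian-smoothing-plus-Poisson count
resampling.  At inference the per-model probability vectors are averaged:

    label(i) = argmax_c  p̄_c(i),   confidence(i) = max_c p̄_c(i),
    p̄_c(i) = (1/M) Σ_m p_c^(m)(i)

Cells below a confidence cutoff (0.7 by default) can be left for expert
review; filtering this way trades coverage for higher recall.  The networks
are implemented in a compact, fully deterministic NumPy engine
(`celltyper.nn`), which also exposes guided backpropagation for saliency
analysis: radial profiles of positive gradients separate nuclear markers
(saliency near the cell center) from membranous ones (saliency at the
boundary).

The package also ships the classical route as a baseline — arcsinh-transformed
size-normalized expression (`arcsinh(counts/area / cofactor)`), a 100-tree
depth-2 XGBoost classifier, and percentile landmark gating — plus three
spillover simulators (Gaussian patch, membrane arc with controllable coverage,
border patch) and a synthetic-tissue generator with known ground truth, so the
entire pipeline is testable without downloading any cohort.

## Data layout

* `images/<fov_id>/<protein>.tif` — one single-channel TIFF per protein
  (filename stem = protein name), or `images/<fov_id>.ome.tif` multichannel.
* `segmentation/<fov_id>.tif` — integer label image (0 = background).
* `labels.csv` — columns `fov_id, cell_id, label`.

The tensor cache written by `celltyper prepare` is one compressed `.npz` per
FOV (array `values`, shape `(n_cells, K+2, S, S)`) plus `index.csv` mapping
`(fov_id, cell_id)` to the array offset.

## Worked example

```python
import numpy as np
import celltyper as ct

rng = np.random.default_rng(1)
bundle = ct.generate_scenarios("spillover", rng)     # ~5,100 cells, 8 classes
train, test = bundle.split()

crop = ct.CropSpec(28)
cfg = ct.ModelConfig(n_classes=8, input_channels=12,
                     epochs=10, draws_per_epoch=2000, base_seed=10)
models = ct.train_ensemble(train, crop, ct.AugmentationConfig(),
                           ct.SamplerConfig(), cfg, n_members=3)

preds = ct.predict_bundle(models, test, crop, cells=test.cells.labeled())
report = ct.evaluate_predictions(preds, test.cells)
kept, coverage = ct.filter_by_confidence(preds, 0.7)
print(f"macro recall {report.macro_recall:.3f} +/- {report.macro_recall_sd:.3f}")
print(f"coverage at 0.7: {coverage:.3f}, "
      f"filtered recall {ct.evaluate_predictions(kept, test.cells).macro_recall:.3f}")
```

Output from this exact run:

```
macro recall 0.988 +/- 0.009
coverage at 0.7: 0.980, filtered recall 0.994
```

So the 3-member ensemble recovers the generator's ground-truth classes on
held-out images with 98.8% macro recall despite spillover and noise patches,
and restricting to the 98% of cells predicted with confidence ≥ 0.7 raises
recall further — the confidence score is informative, not decorative.

The same trained ensemble supports the interpretation analyses:

```python
tregs = [r for r in test.cells.labeled() if r.label == "Treg"]
print(ct.gradient_localization(models[0], test, tregs, crop, "Treg",
                               ["foxp3", "cd4"]))
```

```
  channel  mean_radius_at_fraction  n_cells
0   foxp3                    0.925      166
1     cd4                    1.008      166
```

i.e. 60% of the network's saliency for the nuclear marker is already inside
~0.93 cell radii, versus ~1.01 for the membranous marker — the network looks
for each protein where it actually lives.

## Command line

`synthesize`, `prepare`, `train`, `predict`, `evaluate`, `baseline`,
`simulate`, `gradients` — each takes a single YAML/JSON config and `--seed`,
logs to stderr, and writes a `run_manifest.json` (config hash, seed,
versions) next to its outputs.  Example:

```bash
celltyper synthesize --scenario spillover --seed 1 --out data/
celltyper train --config run.yaml --seed 0 --seed 1 --seed 2 --out ckpt/
celltyper predict --config run.yaml --checkpoints ckpt/ --out preds.csv
celltyper evaluate --predictions preds.csv --config run.yaml --out report.json
```

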