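# Methods

## Model

Each cell is classified from a `(K+2, S, S)` tensor: crops of the K protein
channels centered on the rounded centroid (window rows `[r−S/2, r+S/2)`;
out-of-image pixels padded with a constant, 0 by default), a binary mask of
the target cell, and a binary mask of all other cells in the window.  The two
mask channels are disjoint by construction and are re-disjointed after any
mask-perturbing augmentation.  Crop sizes of 60 px suit 0.5 µm/px data and
30 px coarser IMC-resolution data; the synthetic studies in this repository
use 28 px, which covers one 7–10 µm cell and its immediate neighbors at the
generator's scale.

The classifier is an ensemble of M independently seeded CNNs (member *i* is
seeded `base_seed + i`; diversity comes only from initialization and
augmentation randomness).  Probabilities are averaged uniformly; the argmax
(ties broken by lowest class index) is the label and the maximum is the
confidence.  The reference ensemble size is 10; the desk-scale studies here
use 3, which is already enough for the confidence-calibration properties to
appear.  The averaging is computed as `p₀ + mean(pᵢ − p₀)` so that an
ensemble of identical members reproduces the single model bitwise.

The network engine is written in NumPy: 3×3 same-padding convolutions via
im2col matrix products (the input gradient is a convolution with the flipped
kernels, so the whole backward pass is BLAS matmuls), 2×2 max pooling
(first-maximum tie-break), global average pooling, and a linear head.  The
`small_cnn` backbone has three conv blocks of 16/32/64 filters.  Everything
is float64 in training and deterministic given the seed, which is what makes
bitwise pipeline reproducibility and guided backpropagation (below) cheap to
support.  A `resnet50` backbone name is accepted in configs for
compatibility but is not implemented in this engine.  Training uses Adam
(lr 1e-3, the engine's only optimizer), unweighted cross-entropy, batch
size 32, and a stratified 90/10 train/validation split of the labeled cells;
10–40 epochs is the expected range (10 used here, with 2,000 balanced draws
per epoch).

## Class balance and augmentation

Class imbalance (up to 100-fold in tissue) is handled by the sampler, not
the loss: per-epoch draws with replacement, either `equal` (classes
equiprobable) or `lineage` (lineages equiprobable, classes equiprobable
within lineage).  Upsampling is realized as weighted sampling rather than
physical duplication.

Augmentations, in fixed order so seeded runs are reproducible:

1. one of the 8 dihedral transforms of all channels jointly (rotations
   restricted to multiples of 90° to avoid interpolating count data);
2. target-mask perturbation — integer translation uniform in [−5, 5]² and/or
   dilation-or-erosion by a disk of radius 1–5 px (an erosion that would
   empty the mask is skipped); the environment mask is rebuilt to stay
   disjoint; the translation bound mirrors the stated resize bound;
3. independent per-protein-channel integer shifts uniform in [−5, 5]², each
   channel with probability 0.3;
4. Gaussian signal averaging (σ = 1.0, kernel truncated to 5×5 — the window
   is specified, the σ is this package's choice) followed by pixelwise
   Poisson resampling.  This assumes count-valued input, so normalization
   (`none`, Anscombe `2√(x+3/8)`, or per-channel-per-FOV 99th-percentile
   scaling over positive pixels with clipping to [0, 1]) defaults to `none`
   and, when enabled, is applied after augmentation.

Steps 2–4 fire with probabilities 0.5/0.5/0.3-per-channel/0.5; the paper-style
"random subset of augmentations" is realized by these independent gates.

## Expression baseline, gating, interpretation

The expression matrix is `arcsinh((Σ counts over cell pixels / area) /
cofactor)` with cofactor 1 (configurable); "cell size" is taken as pixel
area.  The baseline classifier is XGBoost with `n_estimators=100,
max_depth=2`, other settings at library defaults, optional inverse-frequency
sample weights.  Landmark gating marks a cell for class *c* iff every
defining protein exceeds its column's 20th percentile and every other
protein is at or below its 15th percentile, with per-class overrides
(relaxed lo-percentile, or defining-markers-only).

Guided backpropagation propagates the target-class logit gradient through
each rectifier only where both the forward activation and the incoming
gradient are positive; the final map keeps positive input gradients.  Radial
profiles sum this map in concentric disks of radius 1, 3, …, 17 px around
the crop center (disks, not annuli, because the quantity of interest is the
radius at which a fraction of the total mass is reached), normalize by the
value at the largest radius, and divide the radius axis by the cell radius
`√(area/π)`.  Cells under 50 px area are excluded as too small for spatial
analysis.  The localization statistic is the interpolated normalized radius
at which the cumulative profile reaches 0.6.

## Signal simulators

All three modes first zero the simulated channel (and any declared cognate
channels) inside the cell's crop window, then add counts at sampled
locations:

* `gaussian_patch` — n points from an isotropic normal (σ = 5 px) about the
  cell center plus an offset; counts Poisson(λ = 4).
* `membrane` — points uniform on the band within Chebyshev distance ≤ 5 px
  (configurable) of the cell boundary (cell pixels 8-adjacent to non-cell
  pixels), restricted to a contiguous arc parameterized by angle about the
  centroid and covering a fraction of the boundary.  The nominal sampling
  rate over the full band scales as n/coverage; restriction to the arc
  cancels it, so exactly n effective points are placed and the expected
  total added signal is coverage-independent — which is the premise of the
  coverage sweep (only the spatial concentration varies).  Counts
  Poisson(λ = 1.3).
* `border_patch` — anchor uniform on the boundary, points at uniform
  distance 0–6 px; cells with minor axis < 15 px are skipped so the patch
  cannot cover the whole cell.  Counts Poisson(λ = 1.3).

Patch-overlap analysis binarizes a channel (> 0 by default), dilates with a
3×3 square (a square, not a disk, is the reading adopted for "kernel of
size 3"), labels 8-connected components, and reports per-cell overlap with
the *undilated* signal.

### The membrane-coverage sweep

For each probed cell the cognate source/target signals are removed, the
source marker is re-simulated on the full membrane, and the target marker on
an arc of 100/50/25/12.5% coverage at constant expected total.  Band width
2 px matches the generator's own membrane width (a simulator should imitate
the marker's real staining geometry in the data at hand), and the point
counts (source 200, target 270, λ = 1.3) put the introduced target marker at
the B-cell-typical in-cell total so that it dominates at full coverage and
the classification question is genuinely ambiguous in expression space.
The modified crop is classified by the CNN ensemble and — via re-quantified
expression — by the tree baseline.  The expected signature: the CNN's
fraction of cells assigned to the target class falls as coverage falls,
while the expression baseline, blind to arrangement, does not.

## Synthetic tissue

Cells are ellipses (radius 6.5–9.5 px ≈ 7–10 µm at 0.5 µm/px; axis ratio
0.75–1.0) placed by dart-throwing with touching allowed (centers at least
0.9·(rᵢ+rⱼ) apart; bounded retries, failure raises).  Contested pixels go to
the earlier cell.  Nucleus = concentric ellipse at 50% of the cell radius;
membrane = 2 px inner band.  Per marker, counts are Poisson with the class's
per-pixel mean over the declared compartment (nuclear / membranous /
whole-cell).  Spillover deposits a stated fraction of each cell's membranous
counts as Poisson counts on neighboring cells' pixels within 2 px of the
cell.  Noise patches are Gaussian-located Poisson blobs in random channels;
a configurable fraction is anchored on random cell boundaries, emulating the
debris that adheres to membranes in real cohorts.  Merged-cell errors fuse a
cell into its nearest neighbor in reach (bridging sub-4-px gaps so the fused
label is connected); the surviving record is flagged.  Identical seeds give
bitwise-identical output, and bundles are written in exactly the on-disk
format the loader reads.

Named scenarios (six 768×768 FOVs of 850 cells; four train, two test;
~5,100 cells):

* `separable` — eight classes with disjoint nuclear markers plus shared DNA
  and membrane stains; the upper-bound sanity case.
* `spillover` — a lymphoid-panel analogue (CD4T, Treg, B, CD8T, tumor,
  neutrophil, endothelial, stroma over 10 channels) with 20% membranous
  spillover and 120 noise patches per FOV, half boundary-anchored.  Treg
  carries both a nuclear (FoxP3-like) and a membranous (CD4-like) marker so
  nuclear-vs-membranous saliency can be compared within one class.  Without
  the boundary-anchored artifact class the coverage-sweep direction is not
  learnable from these data — a classifier that has never seen a bright
  concentrated blob on a non-B cell has no reason to discount one.
* `imbalanced` — four classes at 100:1 commonest-to-rarest.
* `merged` — the separable panel with 5% fused-cell errors.

What the generator does *not* emulate: instrument-specific noise physics,
autofluorescence, cell-shape irregularity, projections, batch effects, and
imperfect expert labels.  Passing the synthetic studies therefore shows the
pipeline's machinery is correct and that the claimed qualitative behaviors
(confidence calibration, spillover robustness, subcellular-pattern learning)
are reachable under the stated data model — not that the same recall numbers
transfer to any real cohort.

## Numerical and design choices

* Coordinates 0-based `(row, col)`; bounding boxes half-open; crop center is
  the centroid rounded to nearest pixel.
* Segmentation TIFFs must be integer; float masks are rejected.
* Minor/major axes are the ellipse-equivalent full widths from the pixel
  covariance eigenvalues (standard region-properties convention).
* Resolution downsampling (2×2 kernel only) sums counts (conserving total
  signal) and takes the per-block majority nonzero id, smallest id on ties.
* Argmax ties break to the lowest vocabulary index.
* Border cells are kept and their crops padded (a flag can drop them).
* Probability vectors must sum to 1 within 1e-6; prediction CSVs round-trip
  probabilities to better than 1e-9 (full-precision repr).
* The desk-scale study sizes (5,100 cells, 3 members, 10 epochs × 2,000
  draws, crop 28) are chosen so a full retrain-and-analyze cycle runs in
  minutes on one CPU core while leaving the measured properties far from
  their thresholds.

## Known limitations

* The NumPy engine targets crops of a few tens of pixels; it is not a
  GPU-scale ResNet50 and is not meant to reproduce cohort-scale recall
  numbers on real data.
* Lineage-mode sampling requires a complete class-to-lineage map and there
  is no partial-credit handling for unmapped classes.
* The membrane simulator parameterizes arcs by angle about the centroid,
  which is exact for convex cells only.
* Landmark gating uses per-column percentiles over all cells of the matrix;
  with very few cells the gates degenerate (an all-zero matrix yields no
  landmarks).
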