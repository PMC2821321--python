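# Methods

This note documents the models and procedures phenoplate implements, the
parameter choices that matter, what the synthetic data generator does and
does not emulate, and the numerical conventions. Nothing here reports an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Data model and conventions

Pixel arrays are row-major and 0-based; object ids are 1-based with 0 as
background, following the label-matrix convention of segmentation pipelines.
Measurement tables are CSV with key columns `plate, well, site, object_id`
followed by numeric feature columns; missing feature values are permitted in
tables but rejected at training time, where silent imputation would bias the
classifier. Well names are row letter + 2-digit column ("B02"); layouts
default to 96-well (8×12) with 384-well (16×24) and arbitrary positive pairs
supported.

A trained model is persisted as self-describing JSON — class and feature
names, per-feature (min, max) scaling, support vectors in scaled space, dual
coefficients, intercepts, C, γ and class weights — rather than a binary
pickle, so any implementation can read it and the decision function is
reproduced exactly on reload (the tests assert bit-identical decision
values).

## SVM classification

Classification is a one-vs-one soft-margin SVM with RBF kernel. The
quadratic program is solved by libsvm (via scikit-learn's `SVC`); prediction,
pairwise decision values and boundary scores are computed directly from the
extracted solution inside this package, which is what makes exact persistence
possible. One detail worth recording: for two classes scikit-learn stores the
solution sign-flipped (its decision value favors the second class); the
extraction flips it back so that in all cases the decision value of pair
(a, b) is positive when it favors a, with pairs ordered by the sorted class
list. This convention is verified against `SVC.predict` for k = 2…5.

Choices, with rationale:

* **Scaling** — per-feature linear map of the training min/max to [−1, 1]
  (the libsvm guide's convention); constant features map to 0; test-time
  values extrapolate linearly without clipping. Predictions are invariant
  under per-feature strictly increasing affine transforms of the data, which
  the suite checks.
* **Per-class penalties** — class c uses penalty C·w_c, so minority
  phenotypes can be up-weighted; recall of the up-weighted class is
  non-decreasing in its weight (checked at 3 weight levels on a fixed
  imbalanced set).
* **Vote ties** — one-vs-one prediction is a majority vote; ties break by
  the largest sum of winning pairwise |decision values|, then by class
  order. The boundary-proximity score of an object is the minimum |decision
  value| over the pairs involving its predicted class: 0 exactly on a
  decision surface of that class.
* **Cross-validation** — stratified 5-fold with a seeded shuffle, scaling
  and model refit per fold; the confusion matrix aggregates every held-out
  prediction (rows = trained class). Accuracy is reported as the pooled
  fraction correct, i.e. trace/total of that matrix, which coincides with
  the mean over folds when folds are equal-sized. Stratification keeps small
  classes in every fold; `stratified=False` gives a plain random split.
* **Grid search** — C ∈ {2⁻⁵, 2⁻³, …, 2¹⁵}, γ ∈ {2⁻¹⁵, 2⁻¹³, …, 2³} by
  default (the standard libsvm-guide grid), every point cross-validated with
  the same fold seed; ties resolve to the smallest C, then the smallest γ,
  preferring the least complex model.
* Only the RBF kernel is implemented. Any k ≥ 2 classes are supported.

## Feature extraction

* **Intensity**: min/max/mean/median over the object and over its edge,
  defined as the 1-pixel inner boundary (object pixels with a 4-neighbor
  outside the object).
* **Haralick**: masked pixels are quantized to 8 equal-width grey bins over
  the object's own min–max range; co-occurrence at distance 1 is counted
  only between pixel pairs both inside the mask, symmetrized and normalized
  per direction; the 13 classical statistics are averaged over the 4
  directions. Degenerate objects (no co-occurring pair) raise in strict mode
  and yield missing values during batch extraction so a single 1-pixel
  object cannot abort a plate run. Correlation is defined as 0 when a
  marginal variance vanishes (constant objects).
* **Gabor**: mean response magnitude at 0° and 90° with frequency 0.25
  (4-pixel wavelength) and σ = 2 px by default; the object mean is
  subtracted first so constant objects give exactly (0, 0), and rotating the
  image by 90° swaps the two outputs.
* **Bright region**: three selectors for the brightest sub-region — Otsu
  threshold of the masked intensities, a disk of given radius at the
  intensity-weighted centroid, or the pixels at/above the (1−f) intensity
  quantile with f = 0.05 by default. Contrast is reported as the mean
  difference against the remaining pixels and as a z-score against their
  standard deviation; for the top-fraction method the selected union (all
  qualifying pixels, not just the largest component) also yields solidity
  (area / convex-hull area) and eccentricity (second moments). When the
  selection covers the whole object there is no remainder: a constant object
  reports zero contrast difference (missing z-score), anything else reports
  both as missing.
* **Granularity**: round i erodes the running image with a disk of radius 1
  and reconstructs it under the original; the spectrum entry is the drop in
  mean intensity at that round, the scalar is the sum over 16 rounds by
  default (the tests use 8 rounds on 96-px fixture images for speed). The
  spectrum is non-negative, zero for constant images, and the scalar
  strictly decreases under Gaussian blur on the fixture images — the
  property the focus filter relies on.
* **Geometry**: spot→cell relation assigns each child with ≥ 1 overlapping
  pixel to the parent with maximal overlap, ties to the lower parent id.
  Neighbor graphs connect objects whose disk-dilated masks touch (overlap or
  8-adjacency; distance 0 = touching). Cell expansion assigns each
  background pixel within the maximum distance to its nearest nucleus,
  equidistant pixels to the lower id, implemented with exact per-label
  distance transforms (O(labels × pixels), fine at the image sizes this
  toolkit targets). All three are verified against explicit pixel-loop
  oracles on ≤ 64×64 images.

## Training modes and active learning

The label-collection API mirrors how a screener works: free labeling,
forced-choice random draws (image uniform among non-excluded images, then
object uniform within it — avoiding density bias), correction passes that
display predictions for a whole image but memorize only the objects the user
overrules, boundary candidates (ascending boundary score), and a plate-wide
panel of 10 objects from up to 10 distinct images: the two most confident
positive/negative exemplars (extreme signed decision values) plus 8 boundary
picks, at most one per image while at least 8 images still have eligible
objects. Excluded images are never sampled; candidate generators never
repeat already-labeled objects. Relabeling overwrites but the mode log keeps
the full history.

The active-learning check emulates the interactive boundary mode as
*iterative* querying: 20 random seed labels, then 10 rounds of 5 boundary
candidates with the model refit between rounds, against an arm that adds 50
random labels instead; both models are scored on the full ground truth of a
6-feature, 2-class pool (2 × 250 objects, centroid separation 3 within-class
SDs, spread over 20 pseudo-images). One-shot selection of 50 candidates from
a 20-label model is deliberately *not* used: a training set consisting
almost entirely of near-boundary points generalizes poorly, and the
interactive tool retrains between labeling bouts anyway. Under the iterative
protocol the mean gain over 20 seeds is positive and robust across
neighboring configurations (2–10 features, separations 2–4).

## Vectors and variables

A vector is a per-image binary array over the objects of one parent type,
aligned with the sorted object ids. Sources: class membership (a human
session label overrides the model prediction where both exist, so
corrections propagate into summaries), feature threshold comparisons, child
counts (e.g. "≥ 1 docked spot" defines infected), and neighborhood
membership (≥ 1 edge to a flagged object). Logic vectors AND/OR/NOT
previously defined vectors; the registry rejects undefined references,
parent-type mixing and redefinition, so cycles cannot form and evaluation is
order-independent.

For decompositions into mutually exclusive states (mitotic /
mitotic-neighbor / normal) the precedence is explicit in the definitions:
"neighbor" is AND(near-mitotic, NOT mitotic), so a mitotic cell adjacent to
another mitotic cell counts as mitotic. Crossing the 3 states with the
infected dichotomy yields 6 populations that partition every image's
objects, which the suite asserts.

Image variables are counts, percentages (missing when the reference count is
0) or pass-throughs of direct per-image measurements. Well variables
summarize an image variable over the well's non-excluded images (sum or
mean; a well whose images are all excluded is missing) and may apply a
calculation — a small prefix-expression tree over previously defined
variables with +, −, ×, ÷ (guarded) and log₂. Plate variables summarize a
well variable over user-chosen wells (e.g. the standard wells) and broadcast
into well calculations, which is how log₂(well/standard) normalization is
expressed; on a uniform plate the normalized standards are exactly 0.
Missing values propagate through calculations as missing and export as empty
cells, never as 0. Whether "percent infected" should be an image-level
percentage averaged per well or a well-level ratio of sums is genuinely
ambiguous; both are available and the examples use the ratio of sums, which
weights images by their object counts.

## Focus exclusion

Each image maps to the 2-D point (object count, granularity scalar). A
linear soft-margin SVM with balanced class weights is fitted on z-scored
coordinates from the user's in/out-of-focus labels and expressed back in
original units as w₁·n + w₂·g + b, oriented so the in-focus side is
positive; a manually supplied line is accepted too, since "adjusting a line"
interactively is equally valid. Points exactly on the line count as in focus
(keep data unless clearly bad). Exclusion is a reversible flag on the image
record — never deletion — and is honored by candidate selection and by
well/plate summaries, which the suite checks end to end.

## Reporting

Outlined images paint the 1-pixel inner boundary of every flagged object
(thickened inward to the requested line width) in the color of the first
layer whose vector flags it, over an RGB composition of up to 3 channels
with per-channel min–max stretch; first-match precedence lets "infected
mitotic" take a different color from plain "infected". Variable tables
export to one spreadsheet (sheets: image, well, plate) plus CSV mirrors
written with `%.17g` so float64 values survive the round trip exactly; wells
order row-major (A01, A02, …). Heat maps return the numeric n_rows×n_cols
grid alongside the figure (missing wells NaN, rendered grey); scatter plots
return the sliding-window trend series (points sorted by x, window mean,
step 1 — window size is the caller's choice). Tests assert on the numeric
artifacts; figures are smoke-tested only.

## Synthetic data generator

The generator emulates a docking assay: nuclei as Gaussian blobs (radius
6 px, amplitude 0.5 on a 0.05 noise floor), mitotic nuclei ~1.5× brighter at
0.7× radius with stronger internal speckle (condensed chromatin), cells by
nucleus expansion (12 px), and bacterial spots as 2-px discs placed inside
cells with Poisson rates of 1.5 / 1.0 / 0.3 spots per mitotic / neighbor /
normal cell — a 5× mitotic preference with neighbors intermediate. Defaults:
96-well layout, 4 images per well, ~30 cells per 256×256 image, mitotic
fraction 8%; a blur fraction convolves whole images with a Gaussian (σ = 3)
and records the truth flag. Everything is reproducible from one seed, and
ground truth is written beside — never inside — the measurement tables, so
classifier tests only ever see rendered-image-derived features.

What it does **not** emulate: real point-spread functions (blur is plain
Gaussian), uneven illumination, segmentation errors (label matrices are
correct by construction), cell shape variation beyond disks, and spot
clumping. Passing pipelines on these fixtures therefore demonstrates the
*mechanics* — feature extraction, classification, integration, summaries —
not robustness to real microscopy artifacts.

Feature blobs for classifier tests place k Gaussian class clusters at
eᵢ·(s/√2) with unit within-class SD, so every centroid pair is exactly s
apart in SD units.

## Problem sizes

The test suite and the acceptance script run everything at small scale as a
deliberate design choice: fixture plates of 2–6 wells × 2–3 sites at 96×96
px with ~10–12 cells per image (the generator default of 256×256/30 cells is
for realistic fixtures, not for the suites), 8 granularity rounds on those
images, ≤ 64×64 label matrices for the brute-force geometry oracles, blob
sets of ≤ 250 objects per class, 20 seeds for the statistical suites and 40
repetitions for the label-shuffle null. The full suite runs in well under a
minute on one CPU; the acceptance script in about half a minute.

## Known limitations

* The SVM path supports only the RBF kernel; no probability calibration or
  feature selection.
* `expand_to_cells` is exact but O(labels × pixels); very dense plates at
  large image sizes would want a tiled variant.
* The vector calculation language is deliberately tiny (the five listed
  operators); anything richer belongs in user code on the exported tables.
* Only up to 3 channels compose into outlined-image backgrounds.
* Sessions store labels keyed by object reference; if the upstream
  segmentation changes ids between runs, old sessions do not transfer.
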