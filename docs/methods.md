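# Methods

This note documents the models and procedures implemented in `pestbox`, the
choices made where the design was genuinely open, and what the synthetic
benchmarks do and do not demonstrate.

## Problem setting

Automated insect-trap monitoring produces images with many tiny objects
(typically well under 0.4% of the image area each, ~7.6 annotations per
image), a severely imbalanced class distribution (the most abundant of 24
pest classes outnumbers the rarest by nearly 500x), heavy adhesion/occlusion
between neighbouring insects, and a non-trivial fraction of real but
unannotated objects. `pestbox` implements the post-processing, loss
arithmetic and evaluation machinery for this regime, exercised entirely on
synthetic scenes so that no image data or trained network is required.

## Box geometry

Coordinates are continuous, origin top-left, corner-form boxes with
geometric areas. VOC XML's 1-based inclusive pixel indices are converted on
read (`x1 = xmin - 1`, `x2 = xmax`, half-open), so a one-pixel object has
area 1; the mapping is inverted on write. Whether evaluation IoU uses
inclusive or half-open pixel areas is a convention, not something the data
dictates; the half-open choice makes IoU algebra exact and round-trips
through VOC files. Zero-area boxes are rejected at construction rather than
propagated as IoU 0: no downstream formula has to define behaviour for them.

CIoU loss is `1 - IoU + d²/c² + α_v·v` with `v = (4/π²)(arctan(w_g/h_g) -
arctan(w/h))²` and `α_v = v/((1-IoU)+v)` (`α_v = 0` when the denominator
vanishes, i.e. identical boxes).

## Confluence suppression

For a pair of boxes the four x-coordinates are jointly min-max normalized
(likewise y), and the proximity `P` is the Manhattan distance between
normalized top-left corners plus the one between bottom-right corners.
`P` is symmetric, zero iff the boxes coincide, and bounded by 4. Pairs with
`P < 2` are *confluent*. The weighted proximity is `WP = P / c` with `c`
the confidence: division (not multiplication) is what makes small WP favour
high-confidence boxes, which is the stated intent of the weighting; the
alternative reading of the formula would invert the bias and contradict
"the optimal box is selected from the boxes with small WP values".

The selection loop, per class (a class-agnostic mode exists behind a flag):

1. discard boxes with confidence below 0.05 (the floor applies before
   clustering);
2. repeat until no confluent pairs remain: boxes with no confluent partner
   are retained outright; each remaining box's WP is its minimal P over
   current confluent neighbours divided by its confidence; the globally
   minimal-WP box is retained; every box with `P < removal_threshold` to it
   is removed. Ties on WP go to the higher confidence, then the earlier
   input index.

Normalization is per-pair throughout (cluster membership never changes a
pair's P), so the pairwise proximity matrix is computed once. The removal
threshold defaults to the clustering threshold 2.

**A structural property worth knowing:** under per-pair normalization, two
overlapping same-size boxes *always* have `P < 2` (each axis contributes
`2·offset/span < 2`, and overlap bounds the offset below the span), and two
equal boxes aligned on the same row are confluent at *any* horizontal
separation (the y-term vanishes). Consequences:

* "Isolated" test layouts must separate boxes on both axes (the packaged
  sweeps use diagonals with spacing 3x the box side, giving P = 3).
* With `removal_threshold = 2`, a retained box deletes every overlapping
  neighbour — a strict superset of what IoU-thresholded suppression deletes,
  so confluence can never out-retain DIoU-NMS in dense scenes under that
  setting. The packaged adhesion benchmark (below) therefore runs confluence
  with `removal_threshold = 0.5`: clusters still form at `P < 2` and the
  optimal box is still chosen by minimal WP, but only near-coincident boxes
  (duplicates of the same object) are deleted around it. The cited method
  permits the two thresholds to differ.

NMS and DIoU-NMS baselines are greedy descending-confidence selection (ties
by input order); DIoU-NMS suppresses when `IoU - d²/c² > threshold` (0.5
default), sparing overlaps whose centers are far apart.

## Composite loss

Per scale (13/26/52 cells at 416x416 input, 3 anchors each):

* **Coordinate**: `λ_coord · Σ_obj (2 - w·h) · L_CIoU`, with `w, h` the
  ground-truth size normalized by the input size, so the weight lies in
  (1, 2) and tiny boxes weigh up to ~2x. The normalization is a package
  choice; unnormalized pixel sizes would make the weight negative.
* **Classification**: per-class binary cross-entropy summed over responsible
  slots (both the positive and negative class branches).
* **Confidence (objectness)**: focal-modulated BCE
  `Lf = α[Ĉ(1-C)^γ(-log C) + (1-Ĉ)C^γ(-log(1-C))]`, summed over responsible
  slots plus `λ_noobj` times the background slots. Both terms are **added**:
  a subtracted background term would allow negative loss, which is
  meaningless for a quantity being minimized. The modulator exponent sits on
  the *opposite* probability (`(1-C)^γ` on the positive branch), which is
  what yields both the γ=0 reduction to cross-entropy and the worked
  100x reduction at `p_t = 0.9, γ = 2`.

Ground truth is assigned to exactly one (scale, cell, anchor): the anchor
with the best co-centered width/height IoU across all scales, in the cell
containing the box center at that scale. Slot conflicts go to the larger
box; the loser is dropped with a warning. The positive-slot objectness
label is fixed at 1 (not the predicted IoU).

Defaults: `λ_coord = 1`, `λ_noobj = 0.5` (configurable; standard values for
this loss family), `α = 0.1`, `γ = 0.2` (the tuned values for the 24-class
trap benchmark). Probabilities are clamped to `[1e-7, 1 - 1e-7]` before any
log, so every loss value is finite for inputs in [0, 1]; all finiteness
guarantees in the tests assume this clamp. Everything is elementwise
arithmetic plus reductions, so the math lifts onto autodiff arrays
unchanged.

## Evaluation protocol

VOC-style matching: per image and class, detections at or above the
operating confidence 0.5 greedily claim the highest-IoU unmatched
annotation with IoU ≥ 0.5 (ties by annotation input order). AP ranks *all*
detections with no confidence floor (the operating threshold applies to
precision/recall/F1 and counting); it integrates the all-point precision
envelope, with an 11-point variant behind a flag. Macro means are
unweighted over classes; classes with zero annotations have undefined AP
and are excluded from mAP with a warning rather than counted as 0.

Counting pools retained detections of all classes with confidence ≥ 0.5 per
image against the true object count: RMSE, `R² = 1 - Σ(ŷ-y)²/Σ(ȳ-y)²`
(against the true counts, so it can be negative for a bad counter), an OLS
line of predicted on true counts, and a signed-error histogram with
unit-width integer bins.

## Synthetic scenes

The generator is a pure function of (config, seed):

* **Counts.** The number of *labeled* boxes per image is the calibrated
  quantity (mean 7.6). Since each object is independently unlabeled with
  probability `p_missing_label` (0.1 default; the true missingness rate of
  real trap data is not quantified anywhere, this is a stand-in), the full
  object count is drawn negative-binomial with mean `7.6/(1-p_missing)`;
  binomial thinning then gives the labeled count mean 7.6 exactly.
  Dispersion `r = 8` (variance ≈ 2x Poisson) models bursty trap arrivals
  while keeping the n=5000 calibration check ~2.8 standard errors wide.
* **Sizes.** Relative area is log-normal (median 0.13% of the image,
  σ = 0.7), putting ~94% of boxes below the 0.4% relative-scale mark;
  aspect ratios are mildly log-normal.
* **Imbalance.** Class draws follow the published 24-class instance
  proportions by default (fully overridable).
* **Adhesion.** Each new object starts a cluster with probability 0.25;
  members share the seed's class and are rejection-sampled (cap 1,000
  tries, then an error naming the parameters) until their IoU with the seed
  lands in (0.15, 0.6).

The detector simulator perturbs the *full* object list: per-class detection
probability, corner jitter proportional to box size, Poisson duplicates,
Poisson background false positives, and Beta-distributed confidences for
true and false boxes. Detections of unlabeled objects score as false
positives against the visible annotations — the mechanism by which missing
labels deflate measured precision while recall against the visible labels
stays intact (verified as a test: a perfect detector on 20%-unlabeled truth
measures precision ≈ 0.8, recall 1.0).

`render_scene` draws filled ellipses on a noisy grayscale background —
enough to exercise augmentation geometry, with no claim to photorealism.

What the synthetic world does **not** model: appearance (so nothing here
validates feature extraction), spatially correlated missingness, class
confusion in the simulated detector, or trap-device optics. Passing tests
demonstrate correctness of the algorithms under the stated statistical
structure, not detection performance on real imagery.

## Benchmark fixtures

* **Perfect-detector exactness.** Sparse scenes (3 boxes/image, uniform
  class weights, no adhesion, no missing labels) + a perfect detector must
  give mAP 1.0, RMSE 0, R² 1 through every suppression method. Sparsity is
  required because confluence clusters nearby same-class *true* pairs by
  design (see the structural property above); that is a property of the
  algorithm, not an error, and the fixture isolates pipeline exactness from
  it.
* **Adhesion retention.** Dense same-class clusters (pairwise IoU
  0.55–0.75), 3 duplicates per object on average, jitter 6%, and
  confidences drawn Beta(2,2) — deliberately uninformative about
  localization quality. Here confidence-led greedy suppression keeps
  whichever duplicate scored highest and suppresses its neighbours, while
  confluence retains the box most coherent with its cluster; the benchmark
  asserts confluence covers at least as many ground truths as DIoU-NMS
  (observed margin ~8–12% across seeds). This is a fixture-level statement
  about this regime, not a universal claim.

## Dataset utilities

* **Split**: seeded shuffle, largest-remainder rounding of 70/20/10 (so
  sizes always sum to n; ties to the earlier subset).
* **Augmentation**: only images containing a minority target class
  (defaults to the three rarest classes) are augmented; five variants per
  image, each a random non-empty ordered combination of horizontal flip,
  vertical flip, hue shift (±0.1 of the hue circle; a no-op on grayscale),
  rotation (±15°) and a mild affine (scale 0.9–1.1, shear ±0.1 rad) —
  "five random combinations" is read as five seeded random draws per
  eligible image. Boxes map through the axis-aligned hull of transformed
  corners, clipped to the image, dropped below 1 px² (a variant losing all
  its boxes is dropped with a warning).
* **Anchors**: Lloyd's algorithm under `d = 1 - IoU` with boxes co-centered,
  seeded k-means++-style initialization over distinct pairs, mean-update
  centroids, empty clusters re-seeded at the worst-covered point. Because
  the mean update minimizes squared Euclidean distance rather than 1-IoU,
  an update can occasionally raise the objective; the loop then reverts to
  the previous centroids and stops, which keeps the objective history
  non-increasing. The stock nine-anchor set for 416x416 input ships as the
  package default; `kmeans_anchors` exists to regenerate anchors for
  synthetic data and makes no claim that clustering real data reproduces
  the stock values.
* **Schedule**: linear warm-up from `λ_min = 1e-4` to `λ_max = 1e-3` over 5
  epochs, a 5-epoch plateau (both lengths are package choices; only the
  phases themselves are prescribed), then
  `λ = λ_min + ½(λ_max-λ_min)(1 + cos(π·t/T))` with `t` re-indexed from the
  cosine start, reaching `λ_min` at epoch 200. The curve is continuous at
  both phase boundaries and non-increasing throughout the cosine phase.

## Problem sizes

The packaged checks run at desk scale by choice: 5,000 scenes for generator
calibration, 1,000 random ≤6-box instances for suppression oracle
equivalence, 200 instances for the AP oracle, 30–40 scenes for the
end-to-end fixtures. The full suite completes in well under a minute on one
CPU.

## Known limitations

* The confluence/DIoU-NMS retention comparison depends on the removal
  threshold as documented above; with both thresholds at 2 the comparison
  inverts, by construction.
* γ defaults to 0.2 although one description of the tuning range excludes
  values below 1; the selected value is used and the inconsistency is left
  as found. A related claimed 1000x loss reduction at `p_t ≈ 0.96` is
  arithmetically 625x and is not asserted anywhere.
* `R²` for counting is computed against the true counts (not the regression
  fit), so a constant predictor at the true mean scores exactly 0 and bad
  predictors score negative.
* The augmentation warps interpolate bilinearly and can leave black borders;
  boxes are hulls of transformed corners and therefore loose for large
  rotations.
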