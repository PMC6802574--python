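# Methods

## The problem and the approach

Identifying specimens from images — assigning a fly face to a family, a
beetle habitus to one of three sibling species — is a fine-grained visual
classification problem with modest sample sizes (tens to a few hundred
images per taxon). Training a convolutional network from scratch at these
sample sizes fails; *feature transfer* instead uses a network pretrained on
a generic image task as a frozen feature extractor and trains only a
lightweight classifier on top. This package implements that pipeline
end to end and makes its design space — input size, tap block, pooling
level, fusion, normalization — configurable and measurable.

## Pipeline stages

### Input frames

Images are brought to a square side S ∈ {128, 224, 320, 416, 512} (any
multiple of 32 is accepted) in one of two ways. `preserve_aspect` scales
the image so its larger side equals S, centers it, and fills the remaining
frame with uniform random pixel values on [0, 255], drawn independently per
pixel and channel from a seeded generator. Random filler is deliberately
uninformative: a constant border would make the *amount* of padding — i.e.
the object's aspect ratio — trivially readable and could leak category
information. `distort` resamples both dimensions to S. Resampling is
bilinear; with odd margins the extra pixel goes to the bottom/right; no
segmentation or augmentation is performed. The divisibility-by-32
constraint guarantees that all five max-pool halvings land on integers.

### Backbone

The extractor is the five-block VGG16 layout: blocks c1–c5 of 3×3
convolutions (same padding, ReLU) with filter depths 64, 128, 256, 512,
512, each block ending in a 2×2 max-pool, so block ck's post-pool output
("feature matrix") has spatial side S/2^k. The forward pass is implemented
in numpy (im2col + matmul); no training or fine-tuning ever happens.

Two concrete backbones exist:

* **Pretrained adapter** (`load_vgg16_backbone`): reads the 13
  convolutional kernels/biases of the published ImageNet weights from a
  local `.npz` (layout documented in the docstring) and applies the
  canonical VGG input preprocessing (RGB→BGR, ImageNet channel means) —
  features are meaningless without the preprocessing the weights were
  trained with. Obtaining the weight file is the user's (networked) task;
  without it the loader raises an error pointing at the fixture backbone.
* **Fixture backbone** (`make_fixture_backbone`): one conv layer per block,
  full filter depths, He-scaled Gaussian weights from a seeded generator,
  inputs scaled to [−0.5, 0.5]. Random convolutional features preserve
  color/texture statistics well enough that visually distinct categories
  remain linearly separable, which is exactly what offline tests need; no
  claim is made that they match ImageNet features in quality.

### Descriptors

*Global scheme.* Each fused block's post-pool volume is collapsed to one
value per filter by average (default) or max pooling, giving a length-F
vector per block (256 for c3, 512 for c4/c5; fusing c1–c5 gives 1472).

*Intermediate scheme.* To preserve coarse spatial layout between the
global (1×1) and raw extremes, c3–c5 are first brought to a common grid —
the reference side is c4's post-pool side S/16 (26 at S = 416): c3 is
average-pooled 2×2 stride 2, c4 passes unchanged, and c5 is tapped *before*
its final max-pool so it retains S/16. A one-pixel zero border pads the
grid (26→28) so it divides evenly into N×N cells for N ∈ {2, 4, 7, 14};
N equal to the padded side flattens with no reduction, and N = 1 is plain
global pooling of the **unpadded** matrix — the zero border exists only to
make the side divisible and never enters an average. For S ≠ 416 the same
construction applies with S/16 as the reference side (e.g. at S = 128 the
padded grid side is 10, admitting N ∈ {2, 5, 10}); the valid levels are
checked at configuration time. The intermediate pooling operator defaults
to average, consistent with the globally better average pooling, and is
configurable to max.

Flattening is spatial row-major with the filter index fastest. The order
is arbitrary but fixed: a linear classifier is invariant to any consistent
coordinate permutation (asserted as a test property), but caches and saved
models must agree on one order.

*Fusion* concatenates per-block descriptors of one image in ascending
block order; provenance is checked so vectors from different images cannot
be fused.

*Normalization.* Signed square root (sign(x)·√|x|) compresses the dynamic
range of the descriptor, which helps margin classifiers dominated by a few
large activations; it is applied once, after fusion, and is on by default.
l2 normalization is implemented but off by default (it tends to hurt
here); the zero vector is returned unchanged by convention.

### Classifier

A linear one-vs-rest SVM with squared hinge loss, C = 1.0, tolerance 1e-4
and a 10,000-iteration cap (all configurable, none tuned), fit on the raw
descriptors with no standardization beyond the normalization above.
One-vs-rest scales linearly in the number of categories. The solver yields
decision scores, not probabilities, so top-k suggestion lists are ranked
by raw score with exact ties broken by ascending category order. Binary
problems are expanded to two mirrored score functions so every category
owns a (w, b) pair. On hard, near-inseparable descriptor sets the solver
may stop at the iteration cap with a convergence warning; the fitted model
is still deterministic for a fixed seed and is used as-is.

### Evaluation

Stratified 10-fold cross-validation (each fold the test set exactly once;
no extra re-randomization): per category, record indices are shuffled by a
seeded generator and dealt round-robin to folds, so per-fold counts differ
by at most one, with remainders landing in the lowest-indexed folds. A
category with fewer records than folds triggers a warning, not an error.
Grouped folds deal *specimens* instead of images, stratified by category
at specimen granularity (specimens, not images, are balanced — a
best-effort choice), so no specimen ever spans a train/test split; this is
asserted on every plan. A training split missing a category is recorded in
the report and the fold still evaluated.

Reports carry pooled and per-fold accuracy (accuracy = proportion of exact
label matches; error rate = 1 − accuracy, an identity asserted exactly),
confusion counts, per-category accuracy against sample count, and top-k
correctness for k = 1..3 both cumulatively and per rank (the cumulative
reading answers "was the true label among the top k suggestions"; the
per-rank breakdown shows where it landed).

t-SNE (perplexity 30, clamped below n/3 for small n; PCA initialization;
fixed seed) embeds descriptors in 2-D without ever seeing labels — labels
only color the plot. It is a qualitative diagnostic.

## Synthetic data

`fixtures.generate_image_dataset` draws parametric "beetles": an
elliptical body on a noisy greenish lab background, with a category motif
(hue, stripe frequency, count/size of white spots) and per-image nuisance
variation in body scale (0.62–0.88 of the frame), translation, rotation
and image size (96–160 px, non-square allowed). Images of one synthetic
*specimen* share the same spot placement and differ only in nuisance
variables, emulating datasets that photograph each specimen 4–5 times.

Two difficulty levels, fixed once as the package's study conditions:

* **easy** — hues spread evenly over the color wheel, distinct stripe
  frequencies and spot counts per category. Default shape: 4 categories ×
  12 images, 4 images per specimen. Under the fixture backbone with c4
  global average + signed sqrt + 10-fold CV this is essentially perfectly
  separable (accuracy ≥ 0.95; the pinned run reaches 0.98–1.0).
* **hard** — identical hue and stripes everywhere; categories differ only
  in the number of white spots (3, 6, 9, …) at a fixed spot radius, with
  random per-specimen placement. Shape: 4 categories × 20 images. This is
  a fine-grained task in the spirit of sibling-species discrimination:
  accuracies land well above chance but far from perfect, leaving room for
  the descriptor ablations to show direction (average ≥ max pooling,
  c3+c4+c5 fusion ≥ best single block, asserted as non-strict
  inequalities).

What the fixtures do **not** emulate: photographic texture, specimen
damage, label/pin clutter, inter-image illumination drift, and ImageNet
feature semantics. Passing tests therefore demonstrate the *mechanics* of
the pipeline — geometry, determinism, leakage-free evaluation, the
qualitative value of averaging and fusion — not identification accuracy on
real collections, which additionally needs the pretrained weights.

`generate_feature_testset` provides Gaussian class clusters (centers =
random unit directions × separation, unit noise) for classifier and
evaluation unit tests: separation 0 gives chance-level accuracy, large
separation gives accuracy 1.

## Problem sizes and numerical choices

Tests and the acceptance script use S = 128 and the fixture backbone
(48-image easy runs, 80-image hard ablation grid), which keeps a full
session within a couple of minutes on one CPU while exercising every code
path; the geometry checks additionally run single forward passes at
S = 416 and 224 where the published dimensions (52×52×256; 346,112; 7×7)
arise. Pooling operators are verified against a brute-force window loop to
1e-6 relative error. The 4-point max-margin toy is checked against a
direct constrained quadratic minimization. Per-record padding noise is
derived deterministically from (base pad seed, record index) so datasets
don't share identical filler across images while runs remain bit
reproducible. Feature caching keys on (backbone identity, S, resize mode,
derived pad seed, block, tap point, image path).

## Known limitations

* The ablation grid requires a single tap point per block across variants;
  comparing global c5 (post-pool) against intermediate c5 (pre-pool) in
  one grid therefore needs two grid calls.
* Grouped stratification balances specimen counts, not image counts; with
  very uneven images-per-specimen the per-fold image counts can drift.
* The fixture backbone's random features understate the advantage of
  deeper blocks that pretrained semantics would show; block-ranking
  results on fixtures should not be read as predictions for real data.
* `read_manifest` resolves relative paths against the manifest's
  directory; absolute paths are kept as-is.
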