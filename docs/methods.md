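# Methods

## Model and procedure

The package addresses binary class imbalance by synthesising minority-class
rows. Two generators are provided, both operating in min-max normalized
feature space so that no feature dominates the geometry:

* **Classic SMOTE.** For a minority row `x_i`, pick one of its `k` nearest
  minority neighbours `x_ij` (Euclidean distance, self excluded, distance
  ties broken toward the lower row index) and emit
  `p = x_i + u·(x_ij − x_i)` with `u ~ Uniform[0,1]`. Every synthetic point
  lies on the closed segment between its generating pair.

* **Normal-distribution SMOTE.** Replace the neighbour by the minority
  centroid `x'_center` (per-feature mean) and the uniform coefficient by a
  per-feature Gaussian factor `f_j ~ N(1, s·σ_j⁰)`, where `σ⁰` is the vector
  of per-feature minority sample standard deviations (n−1 denominator) and
  `s > 0` a spread scale. Since `E[f] = 1`, the expected synthetic point from
  any source row is the centroid itself; smaller `s` concentrates points
  harder toward the centre.

Both generators run until the imbalance ratio (minority/majority count)
reaches a target, 0.7 by default — the minimal count is
`max(0, ⌈target·n_maj⌉ − n_min)`, computed in exact rational arithmetic so a
binary-float target such as 0.7 never rounds a whole-number threshold (e.g.
0.7 × 500 = 350) the wrong way. Source rows are consumed by cycling a seeded
random permutation of minority indices, which balances usage of source points
and keeps every expansion bit-reproducible from one seed. The synthetic rows
are fused with the normalized originals; output stays in normalized space,
with an explicit inverse transform available.

### Interpretation of the interpolation factor

The factor is drawn **independently per feature**, with spread `s·σ_j⁰` on
feature `j`. A single scalar factor per sample would use only one number from
the spread vector; the per-feature reading is the only one that uses all of
`σ⁰`, and it preserves the headline property (expected value at the centroid)
feature-wise. A consequence worth noting: per-feature factors do not keep the
synthetic point on the straight line from `x'_i` to the centroid, only near
it.

Synthetic values can land slightly outside [0,1] when a factor exceeds the
range that keeps the affine map inside the unit box. By default they are left
untouched, preserving the stated distributional properties; `clip_to_unit`
opts into clamping.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `sigma_scale` | 1 | multiple of `σ⁰` used as factor spread; canonical grid {1, 2/3, 1/3} |
| `target_ratio` | 0.7 | imbalance ratio at which expansion stops (dimensionless) |
| `k` (classic) | 5 | neighbourhood size; the conventional SMOTE default |
| `clip_to_unit` | false | clamp synthetic values into [0,1] |
| `test_fraction` | 0.25 | stratified hold-out fraction (3:1 split) |
| `cv_folds` | 5 | stratified CV folds on the training portion |
| `expansion_repeats` | 5 | independent expand-and-evaluate runs averaged |
| `ntree` | 100 | forest size; the common default (the per-tree OOB mean needs only the per-tree errors) |

The 0.7 stopping target follows the empirical finding, reported for this
family of methods, that classification quality on UCI medical benchmarks
plateaus once the ratio reaches about 0.7. "Reaches" is read as ≥ with minimal
overshoot: adding one row fewer than the computed count leaves the ratio below
target.

## Evaluation harness

A random forest (scikit-learn implementation; Gini splitting, bootstrap
resampling, `⌊log₂ r⌋ + 1` candidate features per split — floored because a
feature count must be an integer) is scored by stratified k-fold
cross-validation on the 75% training portion of a stratified 3:1 split, and
fold metrics are averaged. Metrics are computed with the minority class as
positive: overall accuracy (historically labelled "AUC" in this literature;
it is not area under the ROC curve and is exposed with an `accuracy` alias),
F-value, G-mean, and OOB error. Ratios with zero denominators (degenerate
folds) return 0 with a warning.

OOB error is the **arithmetic mean over trees of each tree's error on its own
out-of-bag samples** — a literal tree-wise average that differs from
Breiman's aggregated-vote definition, which is exposed separately as
`oob_error_vote` (cross-checked in the tests against scikit-learn's
`oob_score_`). Per-tree out-of-bag index recovery uses scikit-learn's
internal bootstrap helpers, wrapped behind a small compatibility shim.

Two leakage modes: `fold_safe` (default) expands inside each training fold
only and maps the validation fold through the fold's normalization;
`paper` expands the training portion once before CV, reproducing the simpler
historical protocol at the cost of synthetic copies of fold-validation points
leaking into fold-training sets. Direction-of-effect comparisons between
methods are made within a fixed mode. Repeats draw child seeds from a
`SeedSequence` of the master seed, so the whole pipeline is reproducible from
one integer.

## Diagnostics and spread selection

Two scalar diagnostics, always in normalized space:

* **inter-class distance** — Euclidean distance between the per-class
  centroids. Because synthetic points have the minority centroid as their
  expectation, expansion moves this by only O(spread/√count); fixtures show
  shifts well under 0.02.
* **sample variance** — the mean over features of the per-feature sample
  variance (n−1), over all rows or minority rows only (configurable; the
  estimator's exact scope is a genuinely open choice, and the scope switch
  lets users probe both). Synthetic points concentrate toward the centre, so
  expanded minority variance is below the original and increases with
  `sigma_scale`.

`preservation_comparison` tabulates both for the original and each candidate
expansion and flags the scale minimizing each absolute deviation; the
best-preserving scale is the recommended spread.

## Synthetic data generator

`make_gaussian_imbalanced` draws two isotropic Gaussian clouds with chosen
class counts, within-class standard deviation, and centroid separation
(expressed in units of that standard deviation, offset equally along all
axes). Isotropic Gaussians are the minimal structure under which every
property above — centroid preservation, variance shrinkage, ratio stopping,
classifier-benefit direction — is analyzable; count pairs such as 268/500 and
45/149 mimic the shapes of common UCI benchmarks. What the fixture does *not*
emulate: correlated or heavy-tailed features, mixed scales, nominal
codings, label noise, or multimodal minority structure. Passing tests
therefore demonstrate correctness of the algorithms and the direction of
their effects, not effect sizes on real clinical data. Edge-case variants
(constant feature, duplicated points, two-sample minority) exercise the
degenerate paths.

The direction-of-effect check uses 45 minority vs 149 majority rows, 8
features, separation 2σ: imbalanced enough that minority recall is the
bottleneck, overlapping enough that the forest is not already perfect, and
small enough that the full repeated protocol (5 repeats × 5 folds × 100
trees) runs in seconds.

## Numerical choices and degenerate inputs

* Constant features (min = max) normalize to 0.0, are flagged, and warn;
  denormalization restores the stored constant. The round trip is exact to
  1e-12 relative tolerance on non-constant features.
* Rows with missing cells (empty or `?`) are dropped at CSV load and counted
  in the log; any other non-numeric cell is a parse error.
* Minority auto-detection takes the less frequent label; an exact tie goes to
  the label sorting first as a string (deterministic), overridable.
* Normalization min/max are fitted on all rows of the dataset being expanded
  (both classes), not per class.
* An all-constant minority class yields centre copies with a warning rather
  than an error.
* kNN distance ties resolve to the lower row index, making the neighbour
  table (and hence classic SMOTE given a seed) fully deterministic.
* Reported tables round to 4–6 decimals at presentation only; all internal
  computation is full precision.

## Known limitations

* Multi-class problems, nominal features and sparse matrices are out of
  scope; every feature is treated as numeric.
* The per-tree OOB mean is reported for fidelity to the metric suite this
  package implements; for model assessment the aggregated-vote OOB is the
  better-behaved quantity.
* Published diagnostic values for the real UCI benchmarks are not asserted
  anywhere in the test suite, which runs entirely on synthetic fixtures; the
  CLI can reproduce such tables given the downloaded CSV files.
* `sigma_scale` selection scans a fixed grid; the diagnostics are descriptive,
  not an optimiser.
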