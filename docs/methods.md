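# Methods

This note documents the models and procedures implemented in `octaco`,
the parameter defaults and why they were chosen, the synthetic data the
package is validated on, and the limits of what those validations show.

## Pipeline overview

The pipeline classifies retinal OCT B-scans in five disease classes
(ARMD, BRVO, CRVO, CSCR, DME) in four stages: dataset scanning and
stratified splitting, deep-feature extraction with a modified CNN
backbone, ant-colony-optimization (ACO) feature selection, and a
multi-classifier cross-validation benchmark. Each stage persists its
artifact (manifest CSV, feature table, selection JSON, report CSVs), so
stages are independently testable and resumable.

## Dataset splitting

The emulated clinical dataset has per-class counts 738/440/313/748/759
(2,998 images). The 80:20 train/test split is stratified per class with
the test count computed as `round_half_up(0.2 * class_total)` — the only
simple rounding rule consistent with all five published test/train
tallies (148/590, 88/352, 63/250, 150/598, 152/607). Which images land
in the test set is a uniform seeded draw; nothing suggests a
chronological split, and a seeded uniform draw is reproducible.
Accepted image extensions are png/jpg/jpeg/bmp/tif(f), case-insensitive;
other files are skipped with a logged warning.

## Modified backbones

The three architectures are built channel-faithfully in numpy: ResNet-50
(7×7/2 stem, 3-4-6-3 bottleneck stages, 2048-wide global average pool),
DenseNet-201 (growth 32, blocks 6-12-48-32 with halving transitions,
1920-wide pool) and InceptionV3 (factorized inception modules, 2048-wide
pool), instantiated at 224×224×3. The pooled width is a property of the
channel progression and is independent of spatial input size, so tests
may use smaller inputs.

Note a terminology trap in parts of the literature: an *N*×1920 feature
vector is sometimes attributed to InceptionV3, but 1920 is
DenseNet-201's pooled width; InceptionV3 pools to 2048. This package
reports the true architectural widths.

**No pretrained ImageNet weights are distributed.** Convolutional
weights are a fixed He-initialized basis drawn from a seeded generator
(identical across runs and machines for a given seed), and "training"
is a linear probe: the new 5-unit fully connected softmax head is
trained by minibatch SGD (cross-entropy) on pooled features that are
z-scored with train-split statistics. Random convolutional features are
a recognized baseline representation; the head-only scheme keeps every
shape, ordering and determinism contract of a transfer-learning
pipeline while remaining runnable on one CPU. Default schedule: 100
epochs, learning rate 1e-4 (1e-5 is also exposed, as both appear in
practice for this task), minibatch 64. With learning rate 0 the head
weights are provably unchanged.

Preprocessing is minimal and standard: bilinear resize to the input
size, grayscale replicated to three channels, scaling to [0, 1] and
ImageNet channel standardization.

A fourth `tiny` backbone (three conv blocks, 64-wide pool) with the
same interface exists solely so that end-to-end tests and examples run
in seconds; it makes no architectural claim.

## ACO feature selection

State: pheromone δ ∈ R^d, all entries initialized at δ₀ = 1, and
visibility v ∈ R^d. The literal colony-sizing rule Kn = V×d (V samples,
d features) is preserved as a formal cap, but a colony of min(V×d, 32)
subset-building ants is the default — with N×1920 tables the literal
rule is astronomically large, and an "ant" must build a subset for
selection to produce a reduced vector at all.

**Visibility.** The default heuristic is the per-feature Fisher
class-separability ratio: variance of the class means over the mean
within-class variance. Constant features get visibility 0; features
that separate classes with zero within-class variance get twice the
largest finite ratio. A `paper_literal` mode that ties visibility to
the pheromone vector (v = δ) is retained for fidelity experiments; it
is degenerate as a heuristic (it collapses the product rule onto the
pheromone alone) and is not the default.

**Transition.** Pseudo-random-proportional: with probability q₀ = 0.3
an ant greedily takes argmax δ_j^α v_j^β over features not yet in its
subset (ties → lowest index), otherwise it samples p_j ∝ δ_j^α v_j^β.
Defaults α = β = 1. If all remaining weights are zero the distribution
falls back to uniform over the remaining features.

**Fitness.** The quality of a subset is the accuracy of a
1-nearest-neighbor classifier on the subset's columns under one seeded,
stratified 25% holdout that is fixed for the whole run, with features
z-scored by train-half statistics. Fitness is therefore a pure
(cacheable) function of the subset, which also makes the elitist trace
monotone by construction. 1-NN is cheap and parameter-free; the seven
benchmark classifiers are deliberately *not* used inside the loop, to
avoid selection bias toward the evaluation model and a 30-fold cost
increase.

**Updates.** The iteration-best subset deposits its fitness on its
member features, δ_j ← (1−μ)δ_j + μ·fitness (μ = 0.1); depositing raw
visibility instead would make the update fitness-blind. Evaporation
pulls every feature toward the initial level, δ_j ← (1−θ)δ_j + θ·δ₀
(θ = 0.05). Both are convex combinations of positive quantities, so
pheromone positivity is invariant; the evaporation step contracts the
sup-norm distance to δ₀ by exactly (1−θ) per application and has δ = δ₀
as its fixed point.

**Schedule and pruning.** 100 iterations by default. The elitist
best-so-far subset is the selection output; then
`floor(prune_fraction × |subset|)` features (default fraction 0.20,
valid range 0.15–0.20 without an explicit override) are removed by
greedy redundancy pruning: repeatedly drop the feature with the highest
maximum absolute Pearson correlation to the other kept features, ties
broken by lower visibility, then lower index. Pruning operates on the
selected subset, not the full vector. Zero-variance columns are treated
as uncorrelated.

Subset size defaults to round(0.5·d) capped at 512. For
planted-recovery experiments the subset size must be commensurate with
the planted cardinality: with 10 informative among 100 features, a
50-feature subset can never be 70% planted, so recovery benchmarks use
subset_size = 12 (→ 10 kept after 20% pruning). A measured consequence
of correlation pruning: planted features are mutually correlated
through their shared class structure while noise features are not, so
pruning preferentially removes planted features and caps recovery
around 80%.

All randomness flows from one seeded generator; two runs with the same
configuration and seed produce byte-identical selection results.

## Benchmark harness

Seven presets, frozen in a registry (hyperparameters in the MATLAB
Classification Learner style these preset names come from; "subspace
decrement", a typo sometimes seen for subspace discriminant, is accepted
as an alias):

| preset | realization |
|---|---|
| linear/quadratic/cubic SVM | polynomial kernel degree 1/2/3, C = 1, coef0 = 1, one-vs-one |
| cosine KNN | k = 10, cosine distance |
| weighted KNN | k = 10, squared-inverse distance weights, Euclidean |
| subspace KNN | random-subspace bagging, 30 × 1-NN, ceil(d/2) features each |
| subspace discriminant | random-subspace bagging, 30 × LDA, ceil(d/2) features each |

Ten-fold stratified cross-validation is the default mode; an 80:20
holdout mode using the manifest split is also provided, since both
protocols appear in practice and reports record which was used. All
presets are scored on the identical seeded fold partition (its hash is
recorded). Features are standardized per fold with training-fold
statistics only, because SVMs and KNNs on raw deep features are
scale-sensitive. Metrics are computed on the pooled out-of-fold
predictions: accuracy, macro precision and recall (percent), macro
one-vs-rest AUC (SVM decision values are softmax-normalized into
probability-like scores, as the multiclass AUC computation requires),
and wall time per preset. Reports are one summary CSV (Classifier,
Accuracy, Time, AUC, Precision Rate, Recall Rate) plus one confusion
matrix CSV per classifier.

## Synthetic data

**Planted feature tables** have n_informative columns whose class means
are drawn once from N(0, class_sep²) per class (within-class spread
noise_sd), and n_noise iid standard-normal columns; planted positions
are a seeded permutation. Defaults: 5 classes × 100 samples, 10
informative + 90 noise, class_sep = 2, noise_sd = 1 — strong enough
that informative features dominate the Fisher ranking, weak enough that
selection is not trivial. The generator returns the planted index set
and the drawn class means (in provenance) for recovery and calibration
tests.

**Synthetic OCT images** are stylized grayscale band-and-blob textures:
a dark vitreous, a bright gently curved retinal band with a foveal dip,
a slightly brighter choroid, multiplicative gamma speckle, and one
lesion archetype per class — drusen-like bumps (ARMD), hemilateral band
thickening (BRVO), diffuse thickening with dark blobs (CRVO), a single
sub-band serous dome (CSCR), multiple intraretinal cysts (DME).
Default geometry draws each image's size from 1000–1050 × 300–350 px,
the range typical of the emulated scanner output; default per-class
counts are the clinical distribution divided by 20 (37/22/16/37/38).
Images are pure functions of (spec, seed): reruns are byte-identical.

These generators exercise I/O, training loops, shape contracts and the
statistical behavior of the selector and harness. They are **not**
anatomically faithful: passing tests demonstrates correctness of the
machinery and recovery of planted structure, not clinical accuracy on
real OCT data, and the headline accuracies reported on clinical archives
are not reproducible from synthetic data.

## Numerical choices and degenerate inputs

- Rounding for split arithmetic: half-up (`floor(x + 0.5)`).
- Transition probabilities are exact to 1e-12 normalization; excluded
  indices are exactly zero.
- Tie-breaks everywhere resolve to the lowest feature index after the
  stated criteria (greedy argmax, pruning order).
- Feature tables are stored as delimited text with full-precision float
  reprs, so save/load round-trips are bit-identical.
- Degenerate requests fail fast with specific errors: test fractions
  outside (0,1), classes with fewer than 2 images, fewer samples in a
  class than CV folds, subsets larger than d, single-class visibility,
  non-finite features, prune fractions outside 15–20% without an
  explicit override.
- Problem sizes in tests and in the acceptance script (planted tables of
  500×100, small d=8 oracle instances, 20-50 ACO iterations where the
  result is provably converged) are chosen so the full suite runs in
  well under a minute of CPU for the statistical parts; they are the
  sizes at which the checked properties are already decisive.

## Per-stage seeding

A single global seed derives one sub-seed per stage as the first state
word of `numpy.random.SeedSequence([global_seed, stage_index])`, taken
mod 2³¹ (stage order: split, train, extract, select, evaluate). Stages
are therefore reproducible in isolation from the run metadata alone.

## Known limitations

- Head-only training: without an autodiff framework the convolutional
  basis is not fine-tuned; representations are weaker than trained
  transfer-learning features, which matters for realism but not for the
  selection and benchmarking machinery validated here.
- The colony-sizing and visibility rules as literally stated (Kn = V×d,
  v = δ) are preserved only as options; the defaults replace them with
  tractable, non-degenerate choices documented above.
- Correlation pruning can discard informative features when the
  informative set is internally correlated (see above).
- The synthetic OCT classes are linearly separable at small image
  sizes; they do not probe robustness to speckle statistics, vendor
  artifacts, or inter-grader label noise.
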