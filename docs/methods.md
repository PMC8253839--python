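# Methods

This note documents the models implemented in `scenesem`, the parameter
choices that matter, what the synthetic-data generators do and do not
emulate, and the numerical conventions and known limitations.

## Object-context embeddings (CBOW with negative sampling)

Each annotated scene is reduced to a deduplicated set of object labels;
multiplicity within a scene is never used. Training enumerates one
(target, context) pair per label per scene, where the context is all other
labels of the scene with equal weight. Scenes with fewer than two labels
contribute no updates but remain in the corpus for counting.

The objective is the standard skip-gram-style negative-sampling loss applied
to the CBOW prediction: with h the mean of the context labels' input vectors
and u_j the output vectors,

    L = -log σ(h·u_target) - Σ_{k=1..K} log σ(-h·u_{j_k}),

with K noise labels per positive drawn from the unigram scene-count
distribution raised to the power 0.75, excluding the current target.
Optimization is plain SGD with a learning rate decaying linearly from its
initial value to 1e-4 of it across the total number of training pairs;
scene order is reshuffled every epoch by the seeded generator. Input vectors
are initialized uniformly in [-0.5/d, 0.5/d], output vectors at zero. The
input-side (context-average) matrix is taken as the embedding. The inner
loop is compiled with numba and is bit-reproducible for a fixed seed on a
fixed machine configuration.

Defaults (`TrainConfig`): dim 10, epochs 1000, negatives 20, learning rate
0.05, min_count 1. These are the reference settings for corpora on the
scale of real annotation datasets (tens of thousands of scenes, thousands
of labels). Two interactions matter at smaller scales:

- **Negatives vs vocabulary size.** Negative sampling implicitly factorizes
  a PMI matrix shifted by log K. On an 80-label synthetic vocabulary a
  shift of log 20 ≈ 3 swamps the PMI signal (typical values ~1), and the
  latent structure washes out; K = 2–5 preserves it. The synthetic-recovery
  tests therefore train with negatives = 2 and learning rate 0.025. The
  default K = 20 is appropriate for the ~3000-label regime.
- **Long training on tiny vocabularies.** With very few labels the exact
  optimum of the objective anti-aligns input vectors of directly
  co-occurring labels (a syntagmatic, not paradigmatic, solution); the
  paradigmatic structure present early in training degrades with more
  epochs. Unit tests on 12-label corpora use ~50 epochs for this reason.
  This is a property of the objective, reproduced by an exact full-softmax
  batch-GD oracle, not of the implementation.

Ensembles train n members with consecutive seeds. Dimensionality comparison
averages each ensemble's Pearson-distance RDMs over the labels of interest
and reports Spearman correlations between the averaged RDMs of every
dimensionality pair. Aggregation concatenates all members' columns,
mean-centers (no scaling — embedding columns share a scale) and keeps the
top principal-component scores, each component's sign fixed so that its
largest-magnitude loading is positive. The same centering and sign
conventions apply to every PCA in the package.

## RDMs, RSA and r_max

Representational dissimilarity is Pearson distance (1 − r) between category
vectors; RDMs are symmetrized and have a zero diagonal. RSA correlation is
the Spearman rank correlation over the strictly-upper triangle only, ties
resolved by average ranks. `r_max` is the signed maximum RSA correlation
over all target-model × nuisance-model comparisons; the sign convention
follows from taking the maximum coefficient rather than its magnitude. A
constant RDM (all distances equal) makes the comparison undefined; the
stimulus-design optimizer treats such states as +∞ (never preferred) rather
than erroring, since random search can legitimately propose them (e.g. one
candidate assigned to every item).

## Stimulus-design optimizer

Items (stimuli) each receive one candidate feature set; candidate features
are averaged within category per layer before RDM construction, so multiple
items per category are supported. Initialization samples a fixed candidate
pool and keeps the best of N random assignments; hill climbing then
resamples a fresh candidate for one uniformly chosen item per iteration and
accepts only strict improvements of r_max (ties rejected). The run stops at
the proposal budget or at the first accepted state below the stop
threshold. The trace of accepted values is non-increasing by construction
and the whole trajectory is reproducible from the seed. On the 81-category
reference instance the best of 1000 random assignments typically already
lands near r_max ≈ 0 — with 3240 rank-correlated pairs the null spread of a
single comparison is ≈ 1/√3239 ≈ 0.018, and the minimum over 1000 draws of
a max over 10 comparisons is small — so the budget of 20,000 proposals is a
comfortable upper bound for reaching the 0.05 stopping criterion.

## Ratings

Panels are complete subjects × categories matrices on a declared ordinal
scale (size 1–8, stability 1–5). The outlier filter computes all pairwise
Pearson correlations between subjects' rating vectors, each subject's mean
pairwise correlation, and removes subjects farther than 1.5 sample standard
deviations (two-sided) from the mean of those means, in a single pass.
Subjects with constant ratings have undefined correlations and are removed
up front with a warning. If the per-subject means have zero dispersion,
nobody is removed. Retained subjects are averaged per category, unscaled;
centering is left to the encoding stage. The filter assumes outliers are a
minority — a panel where a third of raters answer at random inflates the
dispersion estimate and loses sensitivity.

## Responses and reliability

Beta arrays are (voxel × category × run) with a structural NaN pattern: a
cell is defined only when the category belongs to the run's fold (the
reference design is 9 folds × 9 categories, several runs per fold).
Z-scoring is per voxel per run across that run's categories, with the
population standard deviation; it is idempotent. Voxels with a constant
slice are flagged and propagate as excluded (NaN), never zero-filled.

Split-half reliability correlates the odd-run and even-run mean response
profiles per voxel, odd/even defined on the 1-based chronological position
within each fold's run list. The critical threshold for a one-sided test of
positive correlation is r = t_{1−α, n−2} / √(t² + n − 2); for n = 81
categories and α = 0.05 this is 0.1841. Reliability masks retain voxels
whose cross-subject mean reliability meets the (unrounded) threshold.

## Encoding models

`VoxelEncoder` fits OLS per fold on [intercept | model | nuisance] over the
training categories and predicts held-out categories from the intercept and
model columns only; predictions are concatenated in canonical category
order. Designs are checked for full column rank per fold. Accuracy is the
per-voxel Pearson correlation over all categories. The estimator follows
scikit-learn conventions (rows = categories, fitted attributes with
trailing underscores); `fit_predict_cv` wraps it for voxel × category
matrices.

Permutation inference permutes the category labels of the *predicted*
responses independently within each fold and recomputes the correlation
with the actual responses; p = (1 + #{null ≥ observed}) / (1 + n_perm), so
the smallest attainable p with 5000 permutations is 1/5001 ≈ 2.0e−04. One
seeded permutation stream is shared across voxels, which is required for
ROI averages, interaction tests and preference maps (their statistics are
averaged over the same replicate across voxels/models). FDR correction is
Benjamini–Hochberg. Bootstrap SEs resample categories with replacement
within folds (paired predicted/actual), recompute voxel correlations and
the ROI mean per replicate; replicates yielding a constant vector are
redrawn and counted. Preference maps floor negative accuracies at zero
before differencing (observed and every replicate alike), run two one-sided
tests (A>B, B>A), FDR-correct each, and assign voxels to whichever
direction is significant; flooring precedes any cross-subject averaging.
Weight PCA averages each voxel's model-regressor weights across folds (and
subjects, when several are supplied), runs centered PCA with voxels as
observations, and projects the loadings back through the model matrix to
obtain per-category component scores.

### Known limitation: null calibration of the permutation scheme

Permuting predictions without refitting is anti-conservative when the
predictions are cross-validated from the same data they are evaluated
against: each fold's predictions are functions of the other folds'
responses, which also enter the evaluation, inflating the variance of the
observed correlation relative to the permuted null. At this package's
reference size (81 categories, 9 folds, 8 regressors) the marginal
rejection rate on pure-noise data is ≈ 0.10 at nominal α = 0.05 (measured
with 600 voxels and independent permutation streams). The machinery itself
is calibrated — when predictions are derived from an independent response
sample, null p-values are uniform (a unit test asserts this via a
Kolmogorov–Smirnov check). Users drawing inferences near threshold should
prefer effect sizes far from the null (the floor p-values reported for
strong effects are unaffected) or refit-based permutation schemes.
Cross-validated correlation accuracy also carries the usual small negative
bias under the null (held-out fold means anticorrelate with training
means); it is visible in the synthetic null tests (~−0.06 mean r) and
harmless for the one-sided tests used here.

## Synthetic data

The corpus generator draws, per scene, a latent context uniformly, a scene
size from a shifted negative binomial (default mean 6, dispersion 4,
minimum 2), and labels without replacement from the context's
Dirichlet-weighted label distribution; with probability 1 − purity an
individual label is drawn from a uniformly chosen *other* context's
distribution (renormalized over labels not yet in the scene, so the
own-context fraction is exactly the purity in expectation). Defaults —
2000 scenes, 80 labels, 4 contexts, purity 0.9 — are the package's
reference desk-scale conditions. What the generator does **not** emulate:
Zipf-scale frequency skew of real annotation corpora (Dirichlet(1) weights
are mildly skewed only), polysemy/near-synonym label noise, spatial
adjacency within scenes, and corpus sizes in the tens of thousands.
Passing recovery tests therefore demonstrates the correctness of the
training and inference machinery on structured co-occurrence data, not
performance on any real annotation corpus.

The response generator produces betas = intercept + embedding·weights
(+ optional nuisance contribution) + i.i.d. Gaussian noise per
(voxel, category, run) at the beta level — there is no time-series,
hemodynamic or spatial structure, and no voxel geometry. Weights,
intercepts and noiseless responses are returned as ground truth. Expected
split-half reliability under this generator is s²/(s² + 2σ²/R) per voxel
(s² the noiseless response variance, σ the per-run noise SD, R runs per
fold-pair), which the tests use as a closed-form oracle. The rating
generator rounds and clips honest raters' noisy scores to the scale and
draws outlier subjects uniformly.

All generators take one explicit seed; there is no hidden global state.

## Problem sizes used by the test suite

Unit tests run on deliberately small instances (tens of labels, hundreds of
scenes, ≤ a few hundred voxels, ≤ 1000 permutations); the acceptance checks
use the reference 81-category design with 200–500 voxels, 1000–5000
permutations, a 2000-scene corpus, and the full 3000-candidate/20,000-
proposal stimulus-design budget. The complete suite runs in a few minutes
on one CPU.
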