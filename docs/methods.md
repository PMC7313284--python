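# Methods

## Pipeline overview

`actiseq` classifies time-ordered windows of wearable-sensor features into
activities.  Training proceeds in six stages, all deterministic given the
`random_state`:

1. per-feature affine scaling to [−1, 1] using training extrema;
2. PCA on the scaled features;
3. stratified cross-validated grid search for the SVM kernel width σ and
   base cost C;
4. final one-vs-one weighted SVM on the full training set;
5. out-of-fold SVM label estimates for every training window;
6. supervised HMM fit on (PCA scores, estimated label) observations with
   the true activities as hidden states.

Prediction: scale → project → SVM-label each window → Viterbi-decode the
augmented observation stream.

## Range scaling

Each feature is mapped by x′ = 2(x − lo)/(hi − lo) − 1 with `lo`/`hi` the
training minimum/maximum.  Test values outside the training range are
*not* clipped: the map stays affine, which preserves the geometry the
Gaussian kernel sees; clipping would collapse distinct out-of-range points.
Constant training features map to the midpoint 0.

## PCA

The scatter matrix S = Σ_j (x_j − μ)(x_j − μ)ᵀ is eigendecomposed
(`numpy.linalg.eigh`); eigenvectors are columns sorted by descending
eigenvalue.  The unnormalised scatter form is used rather than the sample
covariance — the eigenvectors are identical and the eigenvalues differ only
by the factor (T − 1), which cancels in explained-variance fractions.
Sign convention: the largest-magnitude entry of each eigenvector is made
positive, so repeated fits (and fits of column-permuted data) are
bit-reproducible.  Ties in eigenvalues keep the stable order returned by
the decomposition.  When the component count is not given explicitly, the
smallest k whose cumulative explained-variance fraction reaches 0.95 is
used — a conventional default exposed as a parameter.

## Weighted SVM

Binary subproblems solve the soft-margin dual

max Σ α_i − ½ Σ α_i α_j y_i y_j K(x_i, x_j),
0 ≤ α_i ≤ C_{class(i)},  Σ α_i y_i = 0,

with the Gaussian kernel K(x, y) = exp(−‖x − y‖²/2σ²).  Per-class box
bounds implement the cost scheme C_i = round(C · m₊/m_i), rounding half
away from zero and flooring at 1, with m₊ the largest class count *of the
training split at hand* (recomputed inside every CV fold).  With equal
class counts every C_i = round(C) and the machine reduces to an ordinary
SVM, which the tests verify against libsvm (scikit-learn's `SVC`).

The solver is sequential minimal optimization with second-order
working-set selection: the first index maximally violates the KKT
conditions; the second maximizes the guaranteed objective decrease.  The
stopping tolerance on the KKT violation is 1e−3 (libsvm's default), the
iteration cap 100,000 with a `ConvergenceError` carrying the residual gap.
Two numerical details matter in practice:

* after each two-variable update, α values within rounding error of a box
  bound are snapped exactly onto it — otherwise a pair pinned at a corner
  can oscillate by one ULP forever while the selection keeps choosing it;
* the bias b is the mean of y_i − g(x_i) over free support vectors
  (0 < α < bound); if none are free, the midpoint of the KKT interval.

Multiclass extension is one-vs-one (the scheme libsvm uses): N(N−1)/2
binary machines, majority voting, ties resolved to the smallest class
index.  Grid search uses stratified k-fold CV (default 5 folds, seeded) and
pooled out-of-fold accuracy; ties prefer smaller C, then smaller σ.  The
default grids are σ ∈ {0.1, 0.2, 0.5, 1} and C ∈ {0.1, 1, 5, 10, 100};
`folds == n_samples` falls back to leave-one-out, since per-class
stratification is impossible there.

## Supervised HMM and decoding

Hidden states are activities 1..N.  The observation at window t is the
pair (z_t, ŷ_t): PCA scores plus the SVM-estimated label.  Emissions
factorize given the state into a diagonal-covariance Gaussian (continuous
part) and a categorical (estimated-label part).  This keeps every estimate
closed-form:

* transitions a_ij from bigram counts of the training labels, with additive
  smoothing α (default 1) so unseen transitions never produce −∞ decoding
  scores; bigrams spanning a subject boundary are excluded;
* the initial distribution π from overall empirical state frequencies
  (per-sequence initial states would be far noisier with few subjects);
* per-state Gaussian means/variances by MLE, variances floored at 1e−6;
* per-state categoricals over estimated labels with the same smoothing α.

Training the HMM on *out-of-fold* SVM labels is deliberate: resubstitution
labels are nearly perfect and would make the categorical part overconfident
about the SVM's test-time reliability.  At prediction time the labels come
from the final full-train SVM — the only option on unlabeled data.

Viterbi decoding runs entirely in log space; subjects decode
independently; ties take the smaller state index at each backtrack step.
`brute_force_decode` is a vectorized exhaustive enumeration (capped at 10⁶
paths) kept as an independent oracle; exact ties there resolve to the
lexicographically smallest optimal path, which coincides with Viterbi's
rule in the fully symmetric cases the tests exercise (with continuous
emissions, exact ties otherwise have probability zero).

## Metrics

Confusion-matrix rows are true activities, columns predictions.  Summary
recall R̄ and precision P̄ are *unweighted (macro) means* of the per-class
values, and the summary F-measure is the harmonic mean 2P̄R̄/(P̄ + R̄) of
those two averages — this is the convention under which the published
activity-recognition summary tables are internally consistent, even where
they are captioned "micro-averaged" (micro-averaging would collapse all
three to plain accuracy for single-label problems).  Metrics are computed
from unrounded internals; display rounding is one decimal, half away from
zero.  A class absent from the truth yields an explicit error (recall is
undefined), never a silent zero.

## Synthetic sequence generator

The generator emulates the structure that makes temporal smoothing
worthwhile, and only that structure: a first-order sticky Markov chain over
activities (A = sI + (1 − s)·1wᵀ, rows normalized), spherical Gaussian
class-conditional features with mean separation d, and imbalance induced
through the chain's stationary distribution (weights w) rather than by
subsampling.  Defaults: N = 4 activities, p = 6 features, T = 500 windows,
stickiness s = 0.95, separation d = 3 (d = 2 is the "moderate overlap"
regime used in the smoothing experiments), unit variance, uniform weights.

What it does **not** emulate: heavy-tailed and autocorrelated sensor
noise, feature correlations within a class, gradual transitions between
activities, and the 561-dimensional engineered feature sets of real
smartphone corpora.  Passing tests therefore demonstrate the *mechanisms*
(cost weighting lifts minority recall; Viterbi smoothing repairs isolated
framewise errors on sticky sequences), not the absolute accuracy figures
achievable on any real dataset.

## Experiment sizes and design choices

* Smoothing-benefit experiments: 10 train/test pairs of 500-window
  4-class sequences at s = 0.95, d = 2, full default grids.  Hybrid
  decoding beats the framewise SVM in all seeds and repairs ≥ 90% of
  isolated single-frame errors inside runs.
* Imbalanced toy: two Gaussians (unit variance, mean distance 1.8) at
  380:20 training windows, base cost C = 1, σ = 1, evaluated on a 20×
  larger draw.  The count-ratio costs (C₁, C₂) = (1, 19) raise minority
  recall by roughly 35 percentage points on average.  With a large base
  cost (C = 10 → C₂ = 190) the minority class can be *over*-weighted into
  memorization on this tiny sample — the ratio scheme is not scale-free,
  a known limitation worth remembering when C is grid-searched.
* Transition recovery: one 20,000-window simulation at s = 0.9 recovers
  every entry of A within ±0.02 (smoothing 1).
* Viterbi validation: 100 random models with N ≤ 4, T ≤ 8 against
  exhaustive enumeration, path-exact and log-probability within 1e−9.

## Other limitations

* The SMO solver materializes the full kernel matrix of each binary
  subproblem — fine up to a few thousand windows per class pair, not
  intended for corpus-scale training.
* Labels must be contiguous 1..N for the HMM stage (every activity must
  occur in training).
* The HMM assumes the SVM's label errors are conditionally independent
  given the state; systematically confusable class pairs violate this and
  temper the smoothing gain.
* Model bundles serialize every parameter as JSON text; float `repr`
  round-trips exactly, making bundles byte-reproducible under a fixed
  seed.
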