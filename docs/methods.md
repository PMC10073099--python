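# Methods

## The model

cABC analysis operates on a set of n non-negative item values x_i. Values
are sorted descending (stable sort, ties keep input order) and the ABC
curve is the polygon through the knots (i/n, Y_i), Y_i the cumulative
normalized sum, with (0, 0) prepended. For descending-sorted data the knot
increments are nonincreasing, so the polygon is concave, starts at (0, 0),
ends at (1, 1), and lies on or above the diagonal.

The knots are interpolated by a **shape-preserving monotone piecewise
cubic (PCHIP)** by default. An unconstrained cubic spline is available
(`interpolation="cubic"`) for concordance experiments, but it can
overshoot on strongly skewed data and then violates curve monotonicity;
boundary searches detect this (minimum sampled slope below zero) and raise
an error pointing back to the shape-preserving default rather than
silently returning a boundary on a non-monotone curve.

Two boundaries are computed on the interpolant:

* **Juran point (A|B)** — argmin over p of p² + (1 − Y(p))², the squared
  distance to the Pareto point (0, 1). A 4096-interval coarse grid
  brackets the minimum; bounded scalar minimization (Brent) refines it to
  an x-tolerance of 1e−9, comfortably below the 1e−6 contract.
* **Break-even point (B|C)** — the smallest p ≥ J_x with slope Y′(p) = 1,
  found as the first sign change of Y′ − 1 on the same grid, refined by
  bracketed root finding (`brentq`). If the slope never drops below 1
  (identity-like data, diagonal curve) the boundary is reported as p = 1
  with a degenerate-flatness flag. An alternative B|C rule — a Juran-style
  nearest-to-Pareto search on the ABC sub-curve of the items right of the
  A|B boundary (`bc_method="juran_subcurve"`) — is exposed because the
  verbal definition of the B|C boundary admits both readings; the slope
  rule is the default and the two agree on the A side by construction.

Counts are obtained from fractions as |A| = max(1, round(J_x·n)) and
|A∪B| = max(|A|, round(B_x·n)); boundaries cut by rank, so tied values may
straddle a boundary (an explicit `keep_ties_together` option widens the
sets to keep equal values together). The partition is invariant to
multiplying all values by any positive constant, but **not** to
translation; an optional `min_to_zero` flag subtracts the minimum before
curve construction and is off by default (the benchmark results for the
unshifted Gaussian N(5, 1), close to the identity line's 50%, indicate the
reference results were produced without the shift).

Zeros are admitted (real importance vectors contain exact zeros) and
always fall to "C"; only an all-zero vector is rejected. Fewer than three
items cannot support a curve: partitioning refuses, unless `force=True`
requests the trivial all-"A" answer.

## Recursion and termination

Recursive cABC applies the partition to the previous "A" set. Before each
level the candidate list is screened, in order:

1. fewer than 3 items → stop (`too_few_items`);
2. KS uniformity p > alpha (default 0.05) → stop (`uniform_distribution`);
3. candidate size ≤ `target_size` → stop (`target_size_reached`); the
   `miller()` preset uses 9, the upper edge of the 7 ± 2 band;
4. depth ≥ `max_depth` → stop (`max_depth`).

The uniformity test is a one-sample Kolmogorov–Smirnov test against
Uniform(min(x), max(x)) with bounds estimated from the sample, so its
p-values are approximate and decisions near the threshold are soft —
different uniformity tests may disagree when p is close to alpha.
Continuing past a uniform list is harmless in the sense that each further
level would simply keep the top ~41% of items. All-identical values are
the identity distribution, which is *not* uniform; the test reports p = 0
with an `identical` flag so the recursion proceeds to the structural
stops. A `defer_uniformity` option skips the check for the initial input,
forcing at least one split on uniform data (useful for demonstrating the
41% fixed point). Since the uniformity check precedes the first split, a
uniform input stops at depth 0 with the full set as the final set.

The classifier-performance criterion is not part of this module: the
recursion accepts a `level_callback` so a caller can stop it, and the
feature-selection pipeline applies its performance rule to the evaluated
levels (below).

## Distribution benchmark

For each named law, replicate samples are partitioned and the subset-"A"
percentage aggregated (mean, SD, and a one-sample Wilcoxon signed-rank
test against the 41% uniform fixed point — the natural one-sample reading
of a comparison "against a fixed value"). Defaults: 20 replicates of
n = 1000, seeded per (seed, replicate) via `SeedSequence` spawning, so
reports are bit-reproducible. Parameterizations: chi-square with 1 df;
lognormal with log-mean 0 and log-SD 3; unit-rate exponential;
Pareto with shape 1.18 and scale 1 (support [1, ∞)); Uniform[0, 100];
Gaussian N(5, 1) with negative draws redrawn rather than clipped, to avoid
a point mass at zero (rejection probability ≈ 3·10⁻⁷ per draw).

Because ABC analysis is translation-sensitive, the Pareto benchmark is the
one place where parameterization conventions visibly matter: the true
scale-1 Pareto yields mean A-shares near 20% at n = 1000, whereas samples
shifted to start at zero (the Lomax convention used by `numpy`'s `pareto`)
yield ~15% with otherwise identical code. The package uses the
mathematically standard Pareto; both values lie well inside the benchmark's
replicate dispersion (SD ≈ 4 percentage points).

## PCA component retention

`eigen_spectrum` decomposes the feature covariance matrix of the raw data
by default; `standardize=True` switches to correlation PCA, excluding
zero-variance columns from standardization and giving them zero loadings.
The covariance default is what reproduces the published handwritten-digits
retention counts (Kaiser-Guttman 47 of 64; cABC levels 14 and 5 with a
uniformity stop), which pin down the convention; component sign is
irrelevant to all outputs. Reconstruction projects the centered/scaled
data onto all components, zeroes the scores of non-retained components,
and back-transforms, so the output always has the input's shape and
reconstruction error is nonincreasing as the retained set grows along the
eigenvalue order.

## Feature-selection pipeline

A stratified 20% holdout is split off first and its labels are never used
for importance computation or boundary calculation — shuffling the holdout
labels leaves the per-level selected sets bit-identical (tested). On the
training part, permutation importances are computed per fold of a repeated
stratified k-fold (defaults 5 × 20), with 50 shuffles per feature and
balanced accuracy as the scoring metric (matching the evaluation metric),
then averaged across folds. Negative mean importances are clamped to zero
before cABC: a negative permutation importance carries the same
"uninformative" message as zero, and the partition requires non-negative
input. If every mean importance is zero the recursion is skipped and only
the full-feature row is reported.

Each level (the full set and every recursion "A" set) is evaluated on the
holdout: an evaluation run refits the classifier on a random 80% resample
of the training rows (the training share of a 5-fold CV run) and scores
balanced accuracy on a random 80% draw of the holdout; draws missing a
class are redrawn. The default is 100 such runs; the level summary is the
median and the 2.5th/97.5th percentiles. Refitting per run is essential:
with a single fitted classifier the percentile interval would reflect only
holdout-resampling noise and be far too narrow to serve as a confidence
statement about the protocol.

The performance criterion selects the **recommended** level: the deepest
level whose CI lower bound stays above `performance_floor` (default 0.5,
chance for balanced two-class data) and whose median has not dropped more
than `accuracy_drop` (default 0.10) below the full-feature median. It is
applied after the trace is computed, so holdout performance chooses the
reporting depth without ever altering which feature sets exist at each
level. A permuted-target control — labels of the whole dataset shuffled
once, then the identical pipeline — is reported alongside; its CI should
cover 0.5.

The classifier is a pluggable scikit-learn-style estimator
(fit/predict); the default is a 100-tree random forest seeded from the
pipeline seed. Hyperparameter tuning, if wanted, belongs inside the
injected classifier (e.g. a `GridSearchCV` wrapper); the pipeline does not
re-specify it, and the permuted control reuses the same factory.

## Synthetic data

The fixture generator produces (a) tiered importance vectors — uniform
draws within per-tier value ranges, e.g. 2 dominant items in [90, 100],
8 helpful in [8, 12], 90 near-zero in [0, 0.2] — and (b) two-class
Gaussian datasets in which the informative features are mean-shifted
between classes by a stated standardized effect size, with all other
features exchangeable pure noise. Defaults for the classification fixtures
are 100 cases, 20 features, 2 informative, effect size 1.0 — a large but
realistic biomarker effect, and small enough that recovery is a
non-trivial test of the pipeline. These fixtures emulate the skewness and
planted-signal structure that drive cABC; they do **not** emulate
correlated feature blocks, batch effects, non-Gaussian marginals, or
class-dependent covariance, so passing tests demonstrate the machinery's
correctness and calibration, not performance guarantees on real cohorts.

## Problem sizes and numerical choices

The test suite and the acceptance script run the simulation study at 20
replicates of n = 1000 (plus n = 10 000 for the large-sample uniform
check) and the pipeline studies at 20 seeds with scaled-down
cross-validation (3 × 2 folds, 5 permutation shuffles, 40 evaluation runs,
25-tree forests) — sizes chosen so the full suite completes in a few
minutes while leaving every statistical margin intact. Boundary searches
use a 4096-interval bracketing grid with 1e−9 refinement tolerance; test
oracles use independent 10⁶–2·10⁶-point grid scans and central finite
differences (h = 1e−7). Ties in sorting are broken by input order (stable
sort); fraction-to-count mapping uses round-half-even via `round`.

## Known limitations

* KS p-values with sample-estimated bounds are approximate; the uniformity
  stop is soft near alpha.
* ABC analysis is not translation-invariant; results depend on the data's
  zero point unless `min_to_zero` is requested.
* cABC cannot repair a flawed importance measure (e.g. inflated
  Gini-impurity importances); it only computes where to cut the ranking it
  is given.
* The pipeline's balanced-accuracy CIs are nonparametric percentiles over
  correlated evaluation runs (shared holdout), so they are descriptive
  intervals of the protocol's variability, not exact coverage intervals.
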