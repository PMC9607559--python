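# Methods

## Problem setting

The package models a scalar molecular property — the plasticizer
substitution factor, a dimensionless loading ratio with the reference
plasticizer fixed at 1 — as a function of a wide descriptor matrix
(tens of molecules, 10²–10³ numeric descriptors).  In this regime the
modeling risk is dominated by selection, not by the regressor: with n ≈ 20–30
and d ≈ 10³, almost any flexible model interpolates the training set, so the
package's core is two descriptor-selection procedures wrapped in leakage-free
evaluation.

## Data handling

Descriptor matrices and target tables are CSV (UTF-8, header row, first
column = molecule id); missing cells are an error, never imputed.  Cleaning
removes zero-variance columns (they carry no information and break min–max
scaling).  Scaling is per-descriptor min–max to [0, 1]; out-of-sample values
may leave [0, 1] and are not clipped by default, preserving the information
that a new molecule is outside the training range (a `clip` flag exists).
Inside cross-validation and final evaluation the scaler (and any PCA) is
fitted on training rows only; for the Kennard–Stone division the scaler is
fitted on all rows, since the division precedes any train/test distinction.

**Kennard–Stone division.**  Distances are Euclidean on min–max-scaled
descriptors so the division is invariant to descriptor units.  The first two
picks are the globally most distant pair; each later pick maximizes its
minimum distance to the picked set.  All ties break toward the lowest row
index (for the first pair: lexicographically smallest index pair), which
makes the division a pure function of the data.  An exhaustive brute-force
reimplementation serves as the oracle in tests on small random clouds.

## Genetic-algorithm selectors

An individual is a d-bit genome (1 = descriptor selected).  Fitness is the
mean per-fold R² of a 5-fold cross-validation of the configured regressor on
the training partition restricted to the selected columns.  Folds are drawn
once per run from the run seed and reused for every genome so that all
individuals compete on identical folds; this removes fold noise from fitness
comparisons at the cost of a fold-specific bias that is irrelevant for
ranking.  The all-zero genome receives −∞ so it can never win selection.
Fitness values are memoized by genome, which makes elitist runs cheap.

Selection is roulette-wheel: probabilities proportional to fitness.  Because
CV R² of poor subsets is negative while roulette weights must not be,
finite fitnesses are shifted by −min + ε before normalizing; the shift
preserves the ordering, and sentinel individuals get weight exactly 0.
Offspring are drawn with replacement via the cumulative-interval rule
NPᵢ₋₁ ≤ r ≤ NPᵢ.  Crossover is single-point (whole-pair probability P꜀ = 0.5
by default); mutation in variants `O` and `RE` is single-point (whole-genome
probability Pₘ = 0.01).

**Elite retention (`RE`).**  After the offspring are evaluated, if the best
offspring is inferior to the best parent it is replaced by that parent.  The
per-generation best fitness is therefore non-decreasing — asserted on every
run in the test suite.  Exact fitness ties keep the offspring (the fresh
genome).

**History-adaptive mutation (`REC`).**  A rolling window (W = 50) keeps the
per-generation best individuals.  For gene j carried by at least one elite in
the window, the raw score is the fitness-weighted mean over the elites
carrying it; raw scores are min–max normalized across genes; genes absent
from every elite in the window score 0.5 exactly; when all raw scores
coincide the min–max map is degenerate and every gene scores 0.5.  The
normalized scores cannot be used directly as flip probabilities (values near
1 would shred every elite), so they are mapped affinely into
[0.001, 0.05] by default (configurable) and applied as independent per-gene
Bernoulli flips, replacing the single-point scheme.  Two readings of the
history rule are possible — high-scoring genes could mutate more (the literal
formula) or less; the literal reading is implemented.  Its observable effect
is a steady churn of the incumbent's genes: genes whose removal is
fitness-neutral (hitchhikers) drift out of the per-generation optima while
genes carrying signal persist, because an offspring that drops one rarely
wins its generation.

**What enters the Monte-Carlo elite sample.**  The per-generation individual
recorded for descriptor ranking (and for the adaptive-mutation history) is
the best *offspring* of the generation, before elite retention; the
best-fitness trace reported to the user is the post-retention population
best.  Recording the retained incumbent instead would, after convergence,
append the same genome every generation, giving every one of its genes —
signal and hitchhiker alike — identical frequency and destroying the
information content of the ranking.  Both readings are consistent with
"optimal individual of each generation"; the pre-retention reading is the one
under which the ranking measures anything.

**Descriptor ranking.**  Descriptors are sorted by the number of recorded
elites containing them, ties broken by the mean fitness of those elites, then
by name.  When the descriptor matrix is available, exactly value-identical
columns are pooled into one descriptor (an elite counts once if it selects
any copy, and the alphabetically first name represents the group): no
regressor can distinguish identical columns, and without pooling duplicated
columns arbitrarily split their counts.  Top-k prefixes of the ranking are
then swept (train, CV and optional test R² per k) and the final size is the
smallest k attaining the maximal CV R².

### Default GA budget and the regimes of the three variants

Defaults are 50 chromosomes and 200 generations, P꜀ = 0.5, Pₘ = 0.01, 5-fold
fitness, initial genomes Bernoulli(0.1) per gene (useful subsets are small
relative to the pool, and sparse starts give the frequency ranking a
fighting chance; an all-zero draw is repaired by setting one random gene).

The three variants separate most clearly in the *exploration-limited* regime
(short budgets): there the adaptive variant's median final fitness clearly
exceeds plain elitism, which exceeds the plain GA.  Given a long budget on an
easy landscape, plain elitism catches up and the `RE`/`REC` medians converge;
the adaptive mechanism buys speed of exploration, not a better asymptote.
Conversely, the *frequency ranking* needs many elite samples to separate
signal genes from hitchhikers, so descriptor-recovery performance improves
with the full default budget.  The package's statistical tests therefore
measure the variant ordering on a scaled budget (60 generations, 30
chromosomes) over 60 generated data sets — the ordering's median gaps are
small (≈ 0.03–0.15) relative to seed noise, so more replicates are used for
power — and measure planted-descriptor recovery at the full default budget.

## Pearson pre-filter and grid search

Candidates with |r(descriptor, target)| ≥ 0.1 are visited in descending
relevance (ties by name) and kept iff their absolute correlation with every
already-kept descriptor is ≤ 0.5 — a deterministic, CFS-like greedy order
(the acceptance order is the output order).  The screened list's prefixes
k = 1, 2, … are crossed with each family's hyperparameter grid (SVR:
C ∈ {0.1, 1, 10, 100} × γ ∈ {0.01, 0.1, 1}; RF: 100/300 trees × depth
{∞, 3, 5}; PLS: components 1…min(k, n−1)); each cell is scored by the mean
per-fold R² over 10 × 5-fold repeated CV.  After k ≥ 2, the loop stops when
the relative improvement of the running best score falls below 0.01
(patience 1); with tolerance 0 the search is exhaustive over k, which is the
oracle used in tests.

## Models and metric

R² = 1 − SS_res/SS_tot with SS_tot centered on the mean of the actual
values; it is undefined (an error, not a NaN) for constant actuals or fewer
than two points.  The cross-validated score is the arithmetic mean of
per-fold R² on held-out folds — the pooled-prediction R² is also reported
but the per-fold mean is authoritative.  PLS/RF/SVR come from scikit-learn;
SVR defaults to RBF with C = 10 and γ = 'scale'; RF to 300 trees.  The
PCA + SVR composite fits min–max scaler → PCA → SVR on training rows only
and reports the cumulative explained-variance fraction of the retained
components.

Because the GA evaluates ~10⁴–10⁵ candidate subsets per run, single-response
PLS fitness uses a minimal NIPALS implementation (`FastPLS1`) that is
prediction-identical to `sklearn.cross_decomposition.PLSRegression`
(asserted to 1 × 10⁻⁹ in the test suite) but two orders of magnitude faster
to construct and fit at these problem sizes.  Min–max scaling is omitted on
this path: PLS standardizes columns internally, so the scaling step is
prediction-neutral.  Everywhere outside the GA loop, scikit-learn estimators
are used directly.

## Synthetic study conditions

The generator's defaults define the package's reference conditions:
n = 30 molecules, d = 200 descriptors, k = 5 informative columns (standard
normal) driving the target with unit effect sizes, Gaussian noise σ = 0.5,
plus 5 constant columns and 5 exact duplicates of randomly chosen informative
columns.  Column positions are shuffled and names are uniform so planted
columns are identifiable neither by position nor by name.  Effect sizes of 1
against σ = 0.5 give per-descriptor marginal correlations of ≈ 0.4 — strong
enough that selection is possible at n = 30, weak enough that it is not
trivial.  Duplicates are exact by default (they stress the redundancy filter
and the pooled ranking); a jitter flag can make them merely collinear.

What the generator does *not* emulate: the block-correlation structure of
real descriptor families, heavy-tailed or discrete descriptor distributions,
and nonlinear structure–property relationships.  Passing recovery tests on
planted linear signal therefore shows the machinery is sound, not that any
particular real descriptor set will yield a good model.

## Numerical and degenerate-input choices

Roulette requires at least one finite fitness (otherwise a
population-collapse error); probability sums are exact to 10⁻¹².  A CV fold
holding out fewer than two points makes per-fold R² undefined and raises
with guidance (leave-one-out is deliberately unsupported under this metric).
An isolated numerical failure inside a GA fitness CV is retried once on
fresh folds, then scored with the sentinel.  `pca_components` exceeding the
data rank bound is an error rather than a silent clamp at fit time, except
inside the pipeline driver, which clamps to the chosen subset size since the
subset is not known when the config is written.

## Known limitations

* Hyperparameter grids are modest and fixed; no nested CV, so reported CV
  scores of *selected* models are optimistically biased — the test-set score
  is the honest generalization figure, and with 5-molecule test sets it has
  large variance.
* The literal history-adaptive rule assigns newly found high-value genes the
  highest mutation rates, which slows their fixation; the variant's
  advantage is exploration speed (see the regimes discussion above).
* Determinism holds per-platform given the seed; across BLAS builds,
  last-bit differences in PLS/SVD may change individual GA trajectories.
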