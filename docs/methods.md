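# Methods

This note documents the models, defaults and numerical choices behind
`phylobrt`, and what the synthetic-data checks do and do not establish.

## Problem setting

A continuous per-species response (here a dimensionless transform of
in vitro TCDD EC₅₀, standing in for receptor-subtype sensitivity class)
is regressed on two groups of predictors: typed species traits and
phylogenetic eigenvectors. Species are not independent samples — shared
ancestry induces correlation — so relatedness must enter the model.
Phylogenetic eigenvector regression (PVR) handles this by representing
the phylogeny as coordinates and letting the learner weigh them against
the traits; the learner is a boosted regression tree ensemble, chosen
because the trait set mixes continuous, ordinal and nominal columns with
missing values and substantial collinearity, which tree ensembles absorb
without variable exclusion or dummy coding.

## Consensus tree

Trees are treated as rooted, as parsed. A clade (tip subset under an
internal node) enters the consensus iff its frequency across the input
set is **strictly greater** than the threshold (default 0.5). Strict
majority is the standard semantics and guarantees pairwise compatibility
of retained clades at threshold ≥ 0.5, so the nesting construction never
conflicts; clades at exactly 50% are excluded. Consensus branch lengths
are arithmetic means over the trees containing the clade (tip branches
average over all trees); this is the common summarising default, chosen
here as a declared convention. Unresolved regions remain polytomies.
Consensus can run on topology-only trees; branch lengths are demanded
only when distances are computed.

## Patristic distances and PCoA

Patristic distance is the branch-length sum on the unique tip-to-tip
path, computed as `depth(i) + depth(j) − 2·depth(lca)`. Tip labels are
sorted, making the matrix independent of node ordering.

PCoA double-centres `−½ D²` (Gower) and eigendecomposes with
`scipy.linalg.eigh`. Choices:

* **Negative eigenvalues** (possible because patristic distances need not
  be Euclidean-embeddable) are recorded but excluded from coordinates and
  from explained-variation fractions; no Lingoes/Cailliez correction is
  applied. Explained fractions are therefore relative to the positive
  part of the spectrum.
* **Positivity floor**: eigenvalues below `1e-9 × max(|λ|, 1)` are treated
  as zero (the centred matrix always carries one numerically-zero
  eigenvalue for the constant vector).
* **Sign convention**: each axis is flipped so its largest-magnitude
  loading is positive; eigenvector signs are otherwise arbitrary and this
  makes outputs reproducible across LAPACK builds.
* **Selection**: the smallest prefix of axes whose cumulative explained
  fraction reaches the threshold, default **0.99**; 0.95 is the
  conventional floor for controlling phylogenetic autocorrelation in PVR.
  Selection is monotone in the threshold by construction.

## Trait table and response

Columns are declared `continuous`, `ordered` (integer codes) or `nominal`
(level lists); the canonical 17-trait schema (9 continuous, 3 ordered,
5 nominal) ships as `DEFAULT_TRAIT_SCHEMA`. Missing cells pass through to
the learner untouched.

Derived traits:

* **Residual testes mass** — OLS residuals of log₁₀ testes mass on log₁₀
  body mass over complete cases (allometric convention; a raw-scale
  switch exists). Requires ≥ 3 complete cases and positive masses.
* **Migration distance** — absolute difference in degrees latitude
  between breeding- and wintering-range midpoints (midpoint = median of
  the north/south extents when extents are supplied). Degrees latitude,
  not kilometres, is the defined unit.

The response maps species → subtype → EC₅₀ and transforms by default to
**z-scored log₁₀ EC₅₀** (population SD): log₁₀ because EC₅₀ spans orders
of magnitude, z-scoring to make it dimensionless and unit-invariant.
`raw` and `log10` transforms are available. All transforms are monotone
in EC₅₀, so species sharing a subtype share a response value and the
number of distinct values is bounded by the number of subtypes. A
single-subtype response is rejected as degenerate.

In the model frame, ordered codes stay single integer columns and
nominal columns stay single code columns over their level lists — the
tree learner consumes levels directly. Rows align by species label.

## Boosting engine

Least-squares stagewise boosting in the `gbm`/`dismo` tradition:

* Trees are grown **best-first**: among current leaves, the split with
  the largest squared-error reduction is applied, up to
  `tree_complexity` splits per tree (default 3, deep enough to express
  two-way interactions). Split-search ties break to the lowest column
  index, then the lowest threshold; across leaves, to the earlier leaf.
* **Nominal splits** search level subsets: exhaustively for ≤ 10 present
  levels (canonicalised as subsets containing the first present level),
  by mean-residual-ordered prefix scan beyond.
* **Missing values** route to the heavier child (more present rows;
  ties left), recorded per node so prediction is well defined.
* Each stage fits the current residuals on a seeded `bag_fraction`
  subsample (default 0.75) and adds `learning_rate` (default 0.01) times
  the tree's prediction.
* **Tree-count selection**: k-fold cross-validation (default 10 folds)
  stratified on response rank, evaluated every `step_size` trees
  (default 50); the count minimising pooled holdout MSE is selected and
  the final model refit on all data to that count. If the trace is still
  falling at `max_trees`, a warning is recorded on the model.
* Deviance is squared error per observation. **Percent deviance
  explained** is `100 (1 − deviance/null deviance)` with the
  cross-validated predictive deviance as the primary figure; the
  training-mode figure is available for comparison and is the
  optimistic in-sample quantity.
* **VI scores** sum split improvements per column over the selected
  trees and scale to a total of 100; never-used predictors score exactly
  0. A model with zero total improvement returns uniform scores with a
  warning.
* **Partial dependence** clamps one column to each grid value across all
  observed rows and averages predictions (≤ 25 quantile points for
  numeric columns, one point per level for nominal columns).
  **Interaction strength** is the variance of the bivariate
  partial-dependence grid after removing its best additive
  (mean + row + column) fit; 0 for additive surfaces or unused columns.
  Because tree ensembles are piecewise constant, partial-dependence
  curves carry quantisation ripple of order the leaf-step size; the
  additive-recovery checks account for this.

Reproducibility: all randomness (bags, folds) derives from
`rng_seed` via `numpy.random.SeedSequence` spawning, so identical
configs give bit-identical models.

## Deviance partition

Group VI shares (trait vs phylogeny) are plain sums of VI scores within
each group, so they sum to 100; absolute shares of the response deviance
are `total_pct × group_share / 100` and sum to `total_pct`. Reports
round to one decimal; machine-readable outputs keep full precision. The
VI chart applies a 0.5% display cutoff; the full table is always
written. No significance tests are attached to VI scores; the
interaction screen is descriptive.

## Synthetic data: what it emulates and what it does not

The generator mirrors the target dataset's *structure*: 89 tips, the
17-trait mixed-type schema, ≤ 13 subtypes on a log-spaced EC₅₀ grid
spanning three orders of magnitude (matching the up-to-1,000-fold
sensitivity range), 5% missing cells (missingness completely at random —
no mechanism is asserted), and a tree set formed by the true Yule tree
plus 24 NNI-perturbed, length-jittered replicates standing in for a
posterior sample.

Defaults (the simulated study conditions): birth rate 1; Brownian
σ² = 1 per continuous trait; Mk jump rate 0.5 for nominal traits
(roughly 1–2 expected state changes root-to-tip at the resulting tree
height); one driver trait (incubation period, coefficient 1);
`phylo_weight` 0.2 (the fraction of systematic response variance carried
by an independent Brownian component on the tree); residual noise SD
0.3. The latent response is quantile-discretised into subtypes, making
the response monotone in the latent ordering. Ordered traits are
quantile-discretised Brownian traits (keeping them ordinal); Yule trees
rather than birth–death keep an analytic height expectation
(Σ₂ⁿ 1/(kλ)) for validation.

What passing recovery tests show: the pipeline attributes influence to
the correct *group* and the correct *driver* when the generative truth
is known, at realistic n. What they do not show: behaviour under real
trait covariance structures (life-history traits co-evolve far more
richly than independent Brownian draws), informative missingness,
measurement error, or model misspecification of the evolutionary
process — so quantitative deviance figures from simulations do not
transfer to any real dataset.

## Problem sizes and runtime defaults in tests and scripts

The shipped BRT defaults (learning rate 0.01, 10 000 trees, 10 folds)
suit a careful final analysis. The test suite and the acceptance script
use deliberately lighter settings — learning rate 0.1, ≤ 250 trees
evaluated every 25, 5 folds — which reach the same selection plateau on
the simulated datasets at a fraction of the cost; these are analysis
knobs, distinct from the simulated study conditions, which stay at their
defaults. Recovery checks run 10 seeds at the full 89-tip scale.

## Known limitations

* Gaussian loss only; no Bernoulli/Poisson families, no monotonicity
  constraints, single-threaded training.
* Consensus assumes rooted input trees and identical tip sets; no
  rerooting or taxon pruning.
* The strict->0.5 threshold guarantees compatibility; thresholds below
  0.5 are rejected rather than resolved greedily.
* The mean-ordered nominal scan above 10 levels is a heuristic and can
  miss the optimal subset (it is exact for the canonical schema, whose
  largest nominal trait has exactly 10 levels).
* Interaction strength is reported in squared response units on the
  partial-dependence grid; it is a screening statistic, not a test.
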