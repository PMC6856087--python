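# Methods

## The prediction problem

A panel of `J` inbred lines is genotyped at `p` biallelic SNPs and
phenotyped for `T` positive-valued traits in `I` environments, with each
environment observing only a subset of lines.  The goal is to predict the
trait values of unobserved (line, environment) cells.  All models share the
additive decomposition

```
y_ij = E_i + g_j + gE_ij + e_ij
```

with fixed environment means `E_i`, genomic effects `g ~ N(0, σ₁² G)`,
interaction `gE ~ N(0, σ₂² I_I ⊗ G)` and residuals `e ~ N(0, σ² I)`.  The
`I_I ⊗ G` structure makes interaction effects independent across
environments while correlated across lines within an environment through
the genomic relationship matrix `G`.

## Genotypes and the relationship matrix

* Quality control retains markers with missing fraction ≤ 0.10 and minor
  allele frequency ≥ 0.05, MAF computed on non-missing calls as
  `min(f, 1−f)` with `f` = mean dosage / 2.
* Missing calls are imputed with the marker's mean dosage.  The rule is the
  least-assumption default; it preserves column means exactly.
* `G = W Wᵀ / p`.  By default the dosage columns of `W` are mean-centered
  first (VanRaden-style realized kinship, the field standard); a
  `center=False` flag uses raw dosages, which is what the bare formula
  reads.  Both paths are exposed because the choice is consequential for
  the diagonal of `G` but not for prediction ranking in our tests.
* Scaling is by `p`, not by `2Σ p_k(1−p_k)`; the simpler scale is absorbed
  by the variance components in every model.
* The Cholesky convention is `G = Uᵀ U` with `U` upper triangular.  When
  `G` is singular or numerically indefinite, the smallest `ε` in the
  geometric ladder `{0, 1e−8, 1e−7, …, 1e−2·trace(G)/J}` that lets
  `G + εI` factorize is used and reported.  The same jittered factor serves
  as the PSD check for simulation inputs: a matrix that exhausts the ladder
  is rejected.

## Synthetic trials

The generator emulates a durum-wheat-style multi-environment trial:

* Markers: independent sites, per-marker allele frequency uniform in
  `maf_range` (default (0.05, 0.5)), Hardy–Weinberg dosages Binomial(2, f),
  missingness Bernoulli (default 2 %).  No linkage disequilibrium,
  population structure or pedigree — relationship signal comes only from
  shared allele draws, which is enough to give `G` meaningful off-diagonal
  spread for estimator tests, but real kinship matrices are blockier.
* Design: each environment draws a uniform number of distinct lines within
  `lines_per_env_range`; designs are redrawn until every line is observed
  at least once.  Desk default: 100 lines × 8 environments with 57–93 lines
  each; `SimulationConfig.paper_scale()` switches to 270 × 43 with 57–193
  lines per environment and 14,163 markers.
* Traits: three positive traits on days-to-heading / grain-yield /
  plant-height-like scales (baselines 75, 5.5, 95; variances chosen so each
  trait's genomic + interaction + residual variation is a few percent of
  its baseline, keeping arctan relative errors in the informative part of
  its range).  Genomic effects share a genetic correlation across traits
  (default 0.3–0.5, configurable); `gE` and `e` are trait-independent —
  the minimal multi-trait extension of the univariate model above.
  Zero variances are honored exactly (effects collapse to 0, no jitter
  noise), which the degenerate-limit tests rely on.
* The generating `E`, `g` and `gE` are returned so that recovery tests can
  compare estimates against truth.

What passing tests on these data do *not* show: robustness to LD structure,
non-Gaussian trait distributions, outliers, or systematic (non-random)
missingness patterns of real trials.

## GBLUP estimation

Two estimators are implemented behind one interface:

* **Gibbs sampler** (default).  Flat priors on `E_i`; multivariate-normal
  full conditionals for `g` (one `J × J` solve per sweep) and for each
  environment's `J`-vector of interaction effects (so unobserved cells'
  `gE` are part of the joint posterior — predictions for held-out cells
  need no separate step); scaled-inverse-χ² full conditionals for the three
  variances with df = 5 and scales set from the training phenotypic
  variance in proportions (0.25, 0.25, 0.50).  Posterior means are
  reported, with sampling standard deviations as uncertainty.  Default
  chain 6,000 iterations / 1,000 burn-in / thin 5; the end-to-end tests and
  the acceptance script use 1,200–1,500 iterations, which recover variances
  within a few percent at the 200-line scale they run at.
  When `fixed_variances` is supplied, the sampler conditions on those
  values (known-variance posterior); its mean then converges to the exact
  solution below, which is how the sampler is validated.
* **Fixed-variance MME solver.**  Henderson's mixed-model equations solved
  densely at user-supplied `(σ₁², σ₂², σ²)` — exact and deterministic, used
  as an oracle in tests and for shrinkage-limit checks.  An interaction
  variance of 0 drops the interaction block, reproducing the
  no-interaction fit exactly.

REML is not provided; between a sampler that matches the Bayesian fitting
practice of this model class and an exact solver for verification, a third
estimator adds surface without adding checkable behavior.

An environment with no training records makes the fixed-effect system
singular and is reported as an explicit error (the CV1 sampler guards
against creating such partitions).

## Networks

* Features: `X = [Z_E, Z_G Uᵀ, Z_GE (I_I ⊗ Uᵀ)]` (interaction block only in
  I mode).  The Kronecker factor is never materialized: the encoded
  interaction row of cell (i, j) equals the encoded genotype row placed in
  environment block i.
* Architecture: 1–3 hidden layers of equal width, RELU hidden activations,
  RELU output (traits are positive; a linear output is available), biases
  everywhere, inverted dropout (default 30 %) on hidden layers during
  training only.
* Training: MSE summed equally over outputs, mini-batch (32) gradient
  descent with momentum 0.9, learning rate 0.002, global gradient-norm
  clip at 25.  Inputs are standardized per feature on the training set;
  targets stay on their original positive scale.  The output bias is
  initialized at the training-target mean and hidden weights use He
  initialization — with targets on scales up to ~100, these three choices
  (modest learning rate, clipping, mean-initialized output) are what keep
  RELU outputs from collapsing to zero, the failure mode we observed with
  hotter optimization.  Training is deterministic under the spec seed.
* Grid search: for each (units, layers) pair one run of max(epochs) epochs
  records the inner-validation MSE after every epoch, which evaluates every
  (units, epochs, layers) combination at a fraction of the cost of
  retraining per epoch value.  The inner validation split is 20 % of the
  training partition, drawn once per run seed.  Ties break toward fewer
  layers, then fewer units, then fewer epochs.  Default full grid: units
  20–200 step 20 × epochs 1–200 × layers 1–3 = 6,000 combinations; the
  desk-scale default (units {20, 60, 100} × epochs ≤ 50 × layers {1, 2})
  keeps a five-partition six-way experiment within minutes.
* Multi-trait fits drop rows with any missing trait (listwise); univariate
  fits drop only rows missing their own trait.

## Cross-validation and scoring

* CV1 hides `round(0.20·N)` of the `N` observed cells per partition: a line
  is drawn (without replacement when `J` ≥ the target count, with
  replacement otherwise), then one of its observed environments uniformly.
  Collisions on an already-selected cell are redrawn so the test set is a
  set of distinct cells — a duplicated cell adds no information and would
  break the train/test complement.  A cell that would leave its environment
  with no training record is inadmissible and redrawn.  The five partitions
  are drawn independently, so a cell may be tested in several partitions.
* MAAPE: `mean arctan|(y − ŷ)/y|`; a zero observation scores π/2 against a
  nonzero prediction and 0 against a zero prediction.  Per-environment
  MAAPE is computed within each partition and averaged (unweighted) over
  the partitions in which the environment has test cells; cross-environment
  range/mean/median and per-environment winner tallies are reported per
  model × interaction × trait.

## Orchestration

`run_experiment` executes QC → GRM → Cholesky → CV1 → (model × interaction
mode) fits per partition → summary report.  Child seeds for every
stochastic stage are derived from the master seed by SHA-256 over
(seed, stage tokens), truncated below 2³¹, so runs are byte-reproducible
and stages are decorrelated.  A failing model run is logged into the
manifest without aborting the others.

## Problem sizes used by the test suite and acceptance script

Unit and property tests run on 3–60-line toys.  The statistical checks use:
200 lines × 10 complete environments (variance recovery, 10 seeds), the
100 × 8 × 3 desk-scale experiment with five partitions and the desk grid
(end-to-end bounds), and 30–50-line trials for the directional multi-trait
and noiseless-limit checks.  These sizes were chosen as the smallest at
which the respective statistical signal is stable across seeds.

## Known limitations

* Markers are exchangeable — no LD, so marker-level interpretation is out
  of scope; only the relationship matrix matters downstream.
* The Gibbs sampler assumes a dense `G` inverse is affordable (`J` up to a
  few hundred); no sparse or low-rank path is provided.
* The networks are CPU-bound numpy; the full 6,000-combination grid over
  five partitions is a cluster-scale computation and is gated behind an
  explicit flag rather than being the default.
* MAAPE degenerates when observed values approach zero; the generator
  keeps traits positive by construction, but real data with near-zero
  observations would make per-environment MAAPE volatile.
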