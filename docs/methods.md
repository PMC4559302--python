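# Methods

## Model

Counties (areal units) are modeled as draws from a K-component Gaussian
finite mixture over D standardized clustering variables:

    f(y) = Σₖ πₖ φ(y; μₖ, Σₖ),   πₖ ≥ 0, Σₖ πₖ = 1.

Cluster membership is latent; Bayes' rule gives posterior responsibilities
p̂ₙₖ = P(k | yₙ), and each unit is hard-assigned to its maximum-posterior
component (lowest index on exact ties). The model assumes units are
exchangeable given their covariates — no spatial autocorrelation between
neighboring counties is modeled (a known limitation; see below).

### Estimation

Maximum likelihood by EM. The E-step evaluates responsibilities in log
space (log-sum-exp normalization); the M-step performs
responsibility-weighted ML updates of (π, μ, Σ) under a covariance-family
constraint. Six families are supported, crossing shape
(spherical / diagonal / full) with sharing (equal across components /
per-component). Free-parameter counts are (K−1) + K·D plus 1, K, D, K·D,
D(D+1)/2 or K·D(D+1)/2 covariance terms respectively.

Numerical choices:

* **Convergence**: relative log-likelihood improvement < 1e-8, or 500
  iterations. The log-likelihood sequence is non-decreasing by
  construction; the test suite enforces this within 1e-8 slack.
* **Initialization**: one seeded k-means++ hard partition plus random
  soft-responsibility restarts (2 starts total by default); the best
  converged log-likelihood wins. All randomness flows from a single seed.
* **Degeneracy guard**: covariance eigenvalues are floored at
  1e-6 × (mean data variance). Fits whose final parameters sit on the
  floor are flagged and excluded from model selection by default — a
  component collapsing onto near-duplicate points produces a likelihood
  spike, not a better model.
* In one dimension the six families collapse pairwise to
  {equal, varying}; each distinct model is fitted once and its score
  mirrored across synonyms.
* The EM alternation is compiled with numba when available; the numpy
  implementation is the reference path and the suite checks the two agree.

### Model selection

Every (K, family) cell on the grid is fitted and scored with
BIC = 2ℓ̂ − p·log N. On this orientation **larger is better**; the package
maximizes it. (Equivalently: minimizes −2ℓ̂ + p·log N. Descriptions of this
method sometimes say "smallest BIC" while printing the formula above; the
formula wins, and matches the mclust convention.) Ties break toward smaller
K, then the simpler family. The default grid is K = 1..9 and all six
families; the full BIC table is part of every result for inspection.

## Deprivation index

The SES index is the sum of z-scores (sample SD, N−1 denominator) of four
components: % adults without a high-school degree, % single-female-headed
households, % non-white residents, poverty rate. Standardization is
computed over the full pooled table — per-stratum runs re-standardize
within stratum. Missing values are a hard error; no imputation. The index
mean is exactly 0 over the units it was computed on; this is an analytic
property, not an empirical finding.

## Variable selection

Greedy add/drop search over candidate variables. The evidence that
candidate c clusters, given the current set S, is

    E(c | S) = BIC_clust(S ∪ {c}) − [ BIC_clust(S) + BIC_reg(c | S) ]

where BIC_clust(S ∪ {c}) maximizes BIC over the (K, family) grid restricted
to K ≥ 2 (the K = 1 cell is the "no clustering" alternative, which lives on
the right-hand side), BIC_clust(S) maximizes over the full grid (0 for the
empty set), and BIC_reg is the Gaussian linear-regression BIC of c on S
with ML error variance (intercept-only — the single-Gaussian marginal —
when S is empty). The K ≥ 2 restriction matters: without it, on data with
no cluster structure the joint single-Gaussian model wins on parameter
count alone and the search never rejects anything.

The search: pick the best single variable, then the best second variable,
then alternate best-addition / weakest-removal proposals, accepting on
evidence > 0 (configurable), and stop after two consecutive rejections (or
a 2·D + 20 step budget). Ties in evidence break alphabetically, making the
result invariant to candidate order. If no variable shows positive
first-step evidence, the best single variable is returned with a warning
rather than an empty set. Fits are cached per variable set with a
set-derived seed, so the same set is fitted identically regardless of the
path that reached it, and the recorded trace replays to the final set.

## Cluster comparison

Per variable (clustering variables and outcomes separately — no MANOVA):
classical one-way ANOVA (F = MS_between/MS_within, p from the F
distribution; zero between-variance gives F = 0, zero within- with nonzero
between-variance gives p = 0). Pairwise comparisons use the Tukey–Kramer
form of the HSD test, required because cluster sizes are typically very
unequal: SE = √(MS_within (1/nₐ + 1/n_b)/2), adjusted p from the
studentized-range distribution with (#groups, N − #groups), simultaneous
CIs at 1 − α. The reporting α defaults to 0.001. Significance is invariant
to whether outcomes are tested on raw or standardized scales (the F and q
statistics are location-scale invariant), so raw scales are used. Singleton
clusters are dropped from comparisons with a warning. Cluster description
tables code each cluster's mean per variable as low/medium/high by ranking
cluster means and cutting the rank range at terciles (a lone cluster codes
"medium"); near-tied means make the boundary codes sample-dependent, which
is inherent to any rank rule.

## Synthetic data

The generator emulates the structure of a two-state, 129-county study with
five latent clusters:

* **Latent structure**: mixing weights 38/59/5/16/11 out of 129; cluster
  means on the standardized scale from each cluster's qualitative
  low/medium/high profile, coded low = −1, medium = 0, high = +2; spherical
  within-cluster variance 0.04 (SD 0.2), so unit mean gaps are 5-SD
  separations — chosen so the latent clusters are as clearly recoverable
  as the study design implies.
* **Raw scales**: population density is log-normal
  (exp(4.85 + 1.2·z), median ≈ 128); median income 49 367 + 11 405·z;
  supermarket low-access 16.4 + 10.24·z; unemployment 8.68 + 1.23·N(0,1),
  independent of the latent labels (the clustering-irrelevant column).
  Percent columns are clamped to [0, 100].
* **SES components**: drawn through a Gaussian copula. Each latent
  component column is λ·s̃ + √(1−λ²)·g with λ = 0.7, s̃ the standardized
  SES clustering coordinate and g drawn with residual correlation
  (R − λ²)/(1 − λ²), so the total latent correlation equals the configured
  matrix R (default: the published component correlations, entries
  0.476–0.724) while the summed z-scores track the latent SES coordinate
  with correlation ≈ 0.84. Raw scales are modest-variance percentages, so
  clamping is rare and the empirical correlation converges to R (checked
  at N = 5000 within 0.05).
* **Outcomes**: cluster-specific means (obesity ≈ 25.5–31.5 %, diabetes
  ≈ 9.0–11.2 %, following the clusters' low/medium/high outcome profile)
  plus Gaussian noise (SD 1.5 and 0.6 respectively).
* **NCHS classes**: sampled per county from a cluster-specific frequency
  table; metadata only, never used in fitting.
* **Reproducibility**: one global seed fans out to fixed named substreams
  (labels, clustering block, each auxiliary column), so adding a column
  never perturbs earlier columns, and identical configs give byte-identical
  tables.

What the generator does **not** emulate: spatial autocorrelation between
adjacent counties, real geography, measurement error in small-area outcome
estimates, or the exact marginal summary statistics of any real table.
Passing tests therefore demonstrate that the pipeline recovers structure of
the assumed kind when it is present — not that real county data contains
such structure.

## Problem sizes in tests and the acceptance script

The test suite measures cluster-count recovery over 100 seeds
(N = 300, D = 4, exact 5-SD separation), noise-variable exclusion over 25
seeds, EM monotonicity over 100 randomized fits, and type-I/familywise
calibration over 1000 null simulations. `scripts/acceptance.py` re-measures
the same properties at somewhat smaller replication (40/10/60/500) plus one
full pipeline run at the default 129-county scale; these sizes were chosen
as the package's standard quick-verification configuration.

## Known limitations

* BIC-based selection of K is consistent only as N grows; at N ≈ 129 with
  weak separation it tends to merge adjacent clusters (visible in the
  generator at larger within-cluster variance).
* The greedy variable search is a local procedure; exhaustive or
  alternative selection procedures can keep different sets.
* Hard assignments ignore posterior uncertainty; responsibilities are
  exposed for users who want soft analyses.
* ANOVA/Tukey assume within-cluster normality and homoscedasticity and are
  applied to cluster labels estimated from the same data, so downstream
  p-values are conditional on the clustering, not corrected for its
  selection.
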