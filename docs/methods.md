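# Methods

This note documents the models, estimators and numerical choices behind
`resilnet`, and what the synthetic-data tests do and do not establish.

## Resilient-functioning scores

**Model.** One-component PLSR of the processed outcome block `Y` (n×4) on
the stressor block `X` (n×143). The SIMPLS construction is used: the first
x-weight vector is the leading left singular vector of `Xcᵀ Yc`
(maximizing covariance between the X-score and the outcomes); predictions
and residuals are returned on the centered outcome scale. For one component
SIMPLS and NIPALS give identical predictions; the package exposes
`algorithm="nipals"` and the test suite checks both against an independent
textbook NIPALS loop and against scikit-learn's `PLSRegression`. `X` and
`Y` are mean-centered inside the fit; `X` is not scaled by default (the
outcomes are already variance-1 after preprocessing; a config switch can
z-scale `X`).

**Score.** Each subject's resilient-functioning score is the mean of their
four prediction residuals. All four outcomes are coded higher-is-healthier,
so a positive score means better mental health than the stress history
predicts. The residual columns are *not* re-standardized before averaging:
preprocessing already leaves each outcome with variance 1, and
re-standardizing residual columns would reweight outcomes by how well the
stressor block predicts them, which has no substantive justification.
Scores of exactly 0 go to the low group (the split criterion is "> 0").

**Permutation validation.** The statistic is total explained outcome
variance `R² = 1 − SSE/SST` pooled over the four outcomes. Rows of `Y` are
permuted relative to `X`; the add-one estimator
`p = (1 + #{null ≥ observed}) / (1 + n_perm)` keeps p in (0, 1] and makes
the test exact-conservative under row exchangeability. Default 1000
permutations.

## Pre-processing

- **Outcome scores.** WHO-5 sum (0–25); BSI subscale sums (6–30 over six
  1–5 items) inverted as `(max + min) − raw = 36 − raw`, preserving the
  printed scale.
- **Normalization.** "Normalize" is implemented as the van der Waerden
  rank-inverse-normal transform `Φ⁻¹(rank/(n+1))` with average ranks on
  ties, making the Gaussian machinery downstream defensible for skewed sum
  scores. Configurable (`none` available). Order: normalize →
  z-standardize → OLS-residualize on intercept + age + gender →
  re-standardize.
- **Predictors.** DH frequency, DH severity and LE severity columns
  concatenated (58 + 58 + 27 = 143), any negative code (non-occurrence /
  declined) set to exactly 0, otherwise unscaled. The source description
  mentions 147 prepared predictor variables while its instrument
  inventory implies 143; the assembly is configurable and defaults to the
  143 implied by the instruments — the discrepancy is documented rather
  than hidden. Frequency-severity product terms are not built.
- Gender is a single binary dummy; non-binary codes are rejected with a
  clear error (the source instruments offered two categories).

## Polychoric correlations

Two-step maximum likelihood: thresholds from the inverse-normal transform
of marginal cumulative proportions, then the latent correlation maximizing
the multinomial likelihood of bivariate-normal rectangle probabilities,
optimized on (−0.999, 0.999) by bounded Brent search (xatol 1e−8).
Rectangle probabilities come from an in-package bivariate normal CDF
implementing Genz's quadrature (20-point Gauss–Legendre on the correlation
angle for |r| < 0.925, the transformed tail integral above), accurate to
~1e−14 against `scipy.stats.multivariate_normal` — far inside the 1e−10
budget. Degenerate margins (a single occupied category) are an error;
empty categories are dropped. With complete data, per-item thresholds are
estimated once and shared across pairs. The pairwise matrix is repaired to
positive definiteness (smallest eigenvalue ≥ 1e−8) by iterated eigenvalue
clipping with unit-diagonal restoration whenever needed, and the repair is
flagged.

## Graphical lasso and EBIC selection

The solver minimizes `−log det K + tr(SK) + λ Σ_{i≠j} |K_ij|` by ADMM with
an analytic eigenvalue update for the smooth block and off-diagonal
soft-thresholding for the penalized block (the split variable carries exact
zeros, so edge counts are well defined). It is written to run many small
problems as one batched computation and solves the penalty path
largest-λ-first with warm starts — the permutation network test
re-estimates thousands of 10×10 networks, and that workload shaped the
design. Stopping uses per-problem primal/dual residuals (abs/rel 1e−8 for
single fits, 1e−5 inside the permutation test) with Boyd-style adaptive
penalty; converged problems are frozen out of the batch. KKT violations of
returned solutions are ~1e−9, verified against scikit-learn's
`graphical_lasso` and an independent proximal-gradient oracle in the tests.
`λ = 0` returns the exact inverse.

**Path and selection.** 100 logarithmically spaced penalties from
`λ_max = max |S_ij|` (empty graph) down to `0.01·λ_max`;
`EBIC = −2·loglik + E log n + 4γE log k` with `loglik = n/2 (log det K −
tr(SK))`, `E` the nonzero upper-triangle edge count, `γ = 0.5` — the
de-facto defaults of psychometric network practice. Ties prefer the
sparser (larger-λ) model. Partial correlations are
`w_ij = −K_ij/√(K_ii K_jj)`.

**Variants.** Three weight matrices are first-class outputs per group:
the EBIC-selected network as is ("unthresholded"), the same with edges
below the EBIC-consistent cut-off `√(log(k(k−1)/2)/n)` removed
("thresholded", the estimator default), and dense unregularized partial
correlations from the inverted polychoric matrix.

## Global connectivity

Average node strength `mean_i Σ_{j≠i} |w_ij|`, average expected influence
`mean_i Σ_{j≠i} w_ij`, and average shortest path length with edge distance
`1/|w_ij|` (absent edges non-traversable; `−log|w|` available), Dijkstra
over all pairs, averaged over unordered pairs with disconnected pairs
excluded from the mean and counted, never silently dropped. Under this
convention scaling all weights by c > 1 multiplies strength by c and
divides path lengths by c, so "stronger connectivity ↔ shorter paths" is a
theorem and is asserted as a metamorphic test. A network with no finite
pair raises an error; in direction comparisons an edgeless network is
treated as having no finite path (longer than any finite path length).

## Network comparison test

Global strength is the sum of absolute upper-triangle edge weights of the
EBIC-glasso network. Each of the (default 1000) iterations pools subjects,
permutes group labels preserving group sizes, re-estimates both networks
under identical estimator settings, and records the absolute
global-strength difference; the add-one p-value applies. The items are
treated as Gaussian by default (Pearson correlations feeding the lasso) —
the reference usage of this test, which has not been validated for ordinal
data; polychoric internals are a flag. Iterations whose estimation
degenerates are dropped and counted; more than 5% of them is an error.
Inside the test the λ-path is shortened (20 points by default) since
selection, not path resolution, drives the statistic; calibration is
checked empirically (type-I error within the exact binomial 95% interval
at α = 0.05).

## Synthetic cohort generator

What it emulates: 875 subjects (73% women, age 21.97 ± 3.86), all five
instruments with realistic marginal distributions (hassle frequency
~1.1/item, conditional severity ~1.05/item with severity exactly 0 for
non-occurring hassles, life-event load ~0.74/item, well-being ~3.3/item,
symptoms mostly absent, self-efficacy ~2.9/item), a latent stress factor
with moderate item loadings (0.4), mental-health item loadings chosen from
the instruments' published reliabilities (WHO-5: 0.8; BSI: 0.7), latent
health = `stress_effect·stress + offset` with defaults −0.5 and offset SD
1.0, and group-dependent GSE networks: chain graphs on 10 nodes with edge
partial correlations 0.35 (offset above median) vs 0.15, plus a latent
mean shift of 0.35 for the high group (matching the reported item-level
mean differences of ~0.2–0.4). All randomness flows from one seed through
a single ordered `SeedSequence.spawn` split, making cohorts bit-identical
across runs.

What it does not emulate: item-specific loadings or difficulty structure,
missing data (injectable but off by default), selection effects of the
original recruitment, non-chain network topologies, or any longitudinal
structure. Passing tests therefore establish that the *chain of estimators
behaves correctly under the assumed latent-Gaussian ordinal model* —
not that the original study's numbers are recovered; its raw data are not
public, and no numeric result of the original analysis is asserted.

## Known limitations and degenerate regimes

- Under the default low-connectivity condition (chain pcor 0.15 at
  n ≈ 420/group), EBIC with γ = 0.5 is conservative: the selected low-group
  network is empty in a sizeable fraction of seeds once the small-edge
  threshold is applied (the lasso shrinks 0.15-edges to about the
  EBIC-consistent cut-off ~0.095). Shortest path length is then undefined
  for that network and the pipeline reports the failure rather than a
  number. Direction comparisons and the acceptance script therefore use,
  respectively, the unthresholded networks (with the no-finite-path
  convention) and the dense unregularized variant, under which all three
  measures are always defined.
- The polychoric likelihood is clamped at |ρ| = 0.999; perfectly
  concordant item pairs are reported at the clamp, and matrices containing
  them may require PD repair.
- The permutation NCT inherits the caveat that its Gaussian treatment of
  ordinal items is an approximation; both estimator settings run, and the
  calibration test covers the default (Pearson) setting.
- EBIC sample size `n` is the group's subject count; pairwise-complete
  polychoric estimation with missing data is out of scope (complete cases
  per group).

## Problem sizes used by the test suite

Statistical assertions run at the sizes their claims name: structure
recovery at n = 500 over 50 seeds; PLSR null calibration over 200
replicates of 199 permutations at n = 300; NCT type-I error over 200
replicate tests of 200 iterations at n = 300/group and power over 50
replicates at n = 400/group (Pearson internals, 8-point λ-path); the
connectivity direction over 50 end-to-end cohorts at the default n = 875;
determinism on a 300-subject configuration. These sizes are the package's
standing simulation design and are fixed in `tests/test_acceptance.py`.
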