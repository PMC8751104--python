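# Methods

This note records the statistical model, the estimation machinery, the
numerical choices and the validation design of the `ecgc` package. It is
the companion to the code; module docstrings carry the interface-level
detail.

## Model

Records are `y = X tau + Z u_j + e` per environment *j*, with additive
genetic effects `u_j ~ N(0, G sigma_uj^2)` for a genomic relationship
matrix `G` (VanRaden: `G = W W' / (2 sum p_i (1 - p_i))`, column-centred
doses, monomorphic markers excluded). The reaction-norm decomposition

```
u_j = sigma_uj (beta x_j + u~_j),   beta ~ MVN(0, G sigma_beta^2)
```

implies that the between-environment genetic covariance of the *scaled*
effects satisfies `P_jk = x_j x_k sigma_beta^2 + sigma_jk`, i.e. a
covariate `x` that modulates genetic merit adds a rank-one term
`x x'` to the genetic correlation matrix. The covariate search exploits
exactly this: the Pearson correlation between the off-diagonals of the
similarity kernel `(x_j - xbar)(x_k - xbar)` and of the estimated genetic
correlation matrix, with `r^2` read as the share of genetic-correlation
variance attributable to the covariate. The cross-covariance between
`u~` and `beta` is assumed zero throughout (it is not identifiable from
the quantities the pipeline estimates).

## Estimation

**Single-trait REML (step 0).** For one variance ratio
`lambda = sigma_u^2 / sigma_e^2` the restricted likelihood is maximised
exactly on the profile: fixed effects are projected out, the kinship
factor is rotated to diagonal via an eigendecomposition of the projected
design, and a bounded Brent search on `log lambda` in [−25, 25] finds the
optimum. BLUPs for all GRM varieties (observed or not) follow from
`u_hat = sigma_u^2 G Z' V^{-1} (y - X beta_hat)` using a Woodbury solve.

**Pairwise bivariate REML (step 3).** Every environment pair is fitted
as a bivariate mixed model on records matched by (variety, year);
unmatched records enter as "singles" with one missing trait. The
likelihood is evaluated exactly and cheaply through a canonical
decomposition: with `L L' = G`, `M` the diagonal matrix of per-variety
complete-row counts, and the eigensystem of `L' M L`, the core matrix
factorises so each evaluation is O(q) after a one-time O(q^3) setup;
single rows are handled as low-rank Woodbury corrections. Variance
matrices are parametrised by log-Cholesky factors and optimised with
L-BFGS-B (numerical gradients; Nelder-Mead fallback on failure). The
engine was verified against a dense multivariate-normal likelihood to
~1e-14 relative error (the test suite keeps that oracle). The residual
covariance is only estimated when at least two complete rows exist,
otherwise it is fixed at zero.

**Assembly.** Off-diagonals take the pairwise genetic covariances;
diagonals average the per-pair variance estimates of each environment.
The result is repaired to positive definite (Higham alternating
projections with Dykstra correction — matching R's `Matrix::nearPD`,
against which the implementation is frozen-oracle tested), standardised
to unit diagonal, and re-repaired in correlation mode if needed.
Non-converged pairs are excluded; more than 20% flagged pairs aborts the
assembly.

**Scan and pruning (step 4).** Bonferroni threshold
`alpha / (n_covariates × n_traits)`; at the reference scale
`0.05 / (6510 × 6) = 1.28e-6`. Because overlapping stage windows are
nearly collinear, covariates (as standardised points in R^M) are grouped
by complete-linkage hierarchical clustering; the number of clusters is
chosen by the gap statistic (uniform bounding-box references, first-SE-max
rule) and only the top-r² significant covariate per cluster is retained.

**Slopes and GWAS (step 5).** A variety's sensitivity slope is the OLS
slope of its scaled BLUPs `u_hat_vj / sigma_uj` on the standardised
covariate across environments. Slopes are then the phenotype of a P3D
(EMMAX-style) GWAS: one marker-free REML fit fixes the variance ratio,
markers are tested by GLS in the eigenbasis of `G` (vectorised 2×2
normal equations), two-sided t-tests with n−2 degrees of freedom.
Significance is a Storey q-value threshold (pi0 from a cubic-polynomial
smoother on the 0.05–0.90 lambda grid; BH-style pi0 = 1 fallback below
100 tests, where the smoother is unstable). Significant SNPs closer than
100 kb (strict) chain into regions; each region's stability is the count
of 80% variety subsamples (10 draws) in which any member SNP re-reaches
the full-data threshold, with count ≥ 5 flagged "reliable".

## Simulation studies

`ecgc.simulation` plants `P_jk = x_j x_k + sigma_jk` with `x ~ N(0, I_M)`
and LKJ(eta = 4) noise rescaled so the realised off-diagonal variance
ratio equals a target r². The LKJ draw uses the exact onion construction
(for M = 2 the off-diagonal is `2 Beta(eta, eta) − 1`, variance
`1/(2 eta + 1)` — a closed form the tests check). Each replicate tests
the true covariate and 99 independent normal decoys with the scan's
off-diagonal Pearson test; detection is scored by ROC/AUC pooled across
replicates (a per-replicate ROC with a single positive is degenerate).
Desk-scale default is 200 replicates per grid cell; AUC increases in
both r² and M.

## Synthetic data

The generator draws SNP doses `Binomial(2, p_i)`, `p_i ~ U(0.1, 0.9)`;
slopes `beta` from 3 QTLs (half the slope variance) plus a
kinship-distributed polygenic term; a planted covariate
`x_j ~ U(−0.8, 0.8)` injected into one weather factor so the stage-window
mean over the planted span equals `20 + 5 x_j` exactly (daily noise is
re-centred within each planted stage); residual genetic effects with
exchangeable between-environment correlation 0.3 and variance
`1 − x_j² sigma_beta²` (floored at 0.05); phenotypes with year effects
and residual variance set by h² = 0.5. Reference scale: 300 varieties ×
20 environments × 3 years (18,000 records); tests use one weather factor
and 6 stages (21 covariates) for speed, the 14-factor × 30-stage layout
sits behind a `full_scale` flag. The generator makes no attempt to mimic
real geography or weather marginals — its purpose is a transparent,
analytically checkable truth.

## Validation design

`tests/` checks every numerical component against an independent oracle:
closed-form balanced one-way ANOVA REML for the single-trait fit, a dense
MVN likelihood for the bivariate engine, frozen `Matrix::nearPD` outputs
for the PD repair, loop-based Pearson/VanRaden/q-value/region
implementations, Mann-Whitney for AUC, and closed-form LKJ moments.
`tests/test_acceptance.py` adds the study-level criteria: combinatoric
identities, AUC monotonicity at 200 reps (±0.02 Monte-Carlo noise),
LKJ variance ±0.01 at 10,000 draws, oracle equivalences, and parameter
recovery (h² = 0.5 ± 0.1 with 20 replicates of 300 varieties × 3 records;
r_g = 0.8 ± 0.15 with 20 replicates of 250 varieties × 2 years; mean
slope-recovery correlation ≥ 0.8 and planted-cluster detection in ≥ 8 of
10 seeds at the reference scale; at sigma_beta² = 0 the planted covariate
is Bonferroni-significant in ≤ 1 of 10 seeds). `scripts/acceptance.py`
recomputes all of these from one seed and writes them as JSON.

## Numerical and reproducibility choices

- All randomness flows from one seed through named substreams
  (`stage_rng`), hashed with CRC32 so streams depend only on (seed, name).
- GRM jitter 1e-6 before Cholesky; variance floors 1e-8; optimiser
  parameter guard |log-Cholesky| ≤ 20 to avoid overflow in finite
  differences.
- Record matching between environments pairs duplicate (variety, year)
  keys uniformly at random from the run's substream; leftovers become
  single-trait rows.
- Phenotype cleaning masks values strictly outside mean ± 3 SD per
  environment (n−1 denominator, groups under 3 values skipped).
- MAF filtering is strictly greater than the floor (0.05); "counts > 4"
  is encoded as `subsample_min_count = 5`.

## Limitations

- The residual covariance between a pair's environments is identified
  only through varieties evaluated in both; very sparse designs fall back
  to independent residuals.
- The gap statistic tends to choose many clusters when covariate windows
  form a near-continuum; pruning then keeps more representatives, which
  is conservative rather than wrong.
- The bivariate fits assume a shared kinship and homogeneous residual
  variance within environment; spatial trends within trials are out of
  scope.
- Biological results at real-programme scale depend on restricted
  genotype data and are not reproducible here; validation rests on
  synthetic truth.
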