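# Methods

## Model

All analyses are based on the observation-level linear mixed model

```
y = X beta + Z g + e,    g ~ N(0, K sigma_g^2),    e ~ N(0, I sigma_e^2),
```

with `y` the N phenotypic records, `X` (N × p) the fixed-effect design
(intercept, declared factors with reference coding, optional numerical
covariates and stratification principal components), `Z` (N × n) the 0/1
incidence matrix assigning each record to its genotyped line, and `K`
(n × n) the marker-estimated relationship matrix. The phenotypic
covariance is `V = Z K Z' sigma_g^2 + I sigma_e^2`. Replicated records of
a line share one entry of `g` through `Z`; this is the entire mechanism by
which merging replicated or multi-environment records adds information.

## Kinship

`K = W W' / c` with `W` the line-by-marker matrix of allele counts
centered by twice the allele frequency, and `c = 2 Σ p_j (1 − p_j)` summed
over polymorphic markers (monomorphic markers are excluded from both `W`
and `c`; a fully monomorphic panel is an error). `K` is symmetric PSD by
construction and structurally singular (centering makes its rows sum to
zero); nothing downstream requires `K⁻¹`.

## REML variance components

The restricted likelihood is profiled over the variance ratio
`delta = sigma_e^2 / sigma_g^2`. Let `Q2` be an orthonormal basis of the
complement of col(X) and `lam, U` the eigensystem of `Q2' (Z K Z') Q2`.
With `eta = U' Q2' y` and `q = N − p`, the profiled restricted
log-likelihood is

```
LL(delta) = 0.5 [ q ln(q / 2π) − q − q ln Σ eta_i²/(lam_i + delta)
                  − Σ ln(lam_i + delta) ],
```

maximized by a 100-point grid on log delta ∈ [−10, 10] followed by bounded
scalar refinement (`xatol = 1e-12`); then
`sigma_g^2 = Σ eta_i²/(lam_i + delta) / q`. This is exact REML at the cost
of one `O(N³)` eigendecomposition plus `O(N)` per candidate delta; the
deterministic grid-plus-refinement search needs no starting values and
flags (but does not reject) optima at the search bounds. Maximum
likelihood is available behind `criterion="ml"`.

The reported log-likelihood includes a `− ln|X'X|` offset making it
invariant to full-rank reparameterizations of `X` (coding choices do not
change the reported value). Fixed effects and their covariance come from
GLS on the eigenbasis of `Z K Z'` without forming `V⁻¹`.

Numerical note: the profile around the optimum is flat to `O((Δ log
delta)²)`, so independent eigendecompositions of row-permuted data can
move the argmax by ~√machine-epsilon. Fits are reproducible to ~1e-6
relative in the variance components (and far better in the likelihood),
not bit-identical across observation orderings.

## Association scan

Single-marker Wald tests with null variance components held fixed across
markers (P3D). With `V = U D U'` from the null fit, whiten everything by
`D^{-1/2} U'`; for marker `j` with whitened, fixed-effect-residualized
genotype vector `w_r`:

```
effect = w_r' y_r / ||w_r||²,   se = 1 / ||w_r||,   wald = (effect/se)²,
```

referred to χ²₁. The implementation residualizes implicitly — with `Q_x`
an orthonormal basis of the whitened fixed effects,
`||w_r||² = ||w~||² − ||Q_x' w~||²` — so the scan is a single
`(N × N)(N × m)` matrix product plus `O(N m)` bookkeeping: `Θ(N² m)`
total, which the test suite verifies empirically (log–log slope of
runtime vs N at fixed m within 2 ± 0.5). Markers monomorphic among the
phenotyped lines or collinear with the fixed effects are reported as
skipped, not tested. `exact` mode refits REML per marker with the marker
in `X` (for verification at small scale).

## Genomic control

`lambda_GC = median(wald) / 0.4549364` (the χ²₁ median); adjusted
statistics are `wald / lambda_GC` with P-values from the χ²₁ upper tail.
Deflation (`lambda_GC < 1`) triggers a warning but the adjustment is still
applied, and raw P-values are always preserved alongside adjusted ones.
In QTL simulations `lambda_GC` is typically slightly below 1 because the
kinship matrix is built from all markers, QTLs included, so part of the
signal is absorbed into the random effect.

## BLUP

`g_hat = sigma_g^2 K Z' V^{-1} (y − X beta_hat)`, evaluated on the
eigenbasis. This direct form is identical to solving Henderson's
mixed-model equations when `K` is invertible but also covers the
structurally singular marker-based `K`. Genotyped lines without phenotype
records are predicted by kinship-block regression,
`g_u = K_uo K_oo⁺ g_o`.

## Simulation generator

Two populations of the same `n` lines grown in two environments.
Genotypes: independent biallelic markers, allele frequencies uniform on
[0.1, 0.9], codes `Binomial(2, f)`, assigned evenly to chromosomes.
`n_qtl` markers are drawn uniformly among polymorphic markers.
Environment-1 effects all equal `qtl_effect_size` = b; environment-2
effects are `rho·b + sqrt(1 − rho²)·b·z` with `z` standard normal, so the
effect pairs correlate at `rho = gxe_correlation` in expectation.
Environment 2 additionally shifts by `env_effect`. Per-environment noise
is drawn, centered, orthogonalized against the centered genetic values and
scaled so that `var(g)/var(y)` (sample variances, ddof = 1) equals
`target_h2` **exactly** in each realization — the heritability control is
deterministic given the genetic values, not merely calibrated in
expectation. Four datasets are emitted: each environment alone, per-line
averages, and the merged long table with an environment factor. Detection
is scored by ranking markers on P-value and sweeping the threshold (ROC),
summarized by the trapezoidal AUC.

Default configuration: 500 lines, 2000 markers on 10 chromosomes, 50
QTLs, `rho = 0.9`, unit environment shift, `target_h2 = 0.5`. The QTL
count is a calibration choice: with ~10 QTLs at h² = 0.5 each marker
effect is so large that every analysis saturates (AUC > 0.99) and the
benchmark cannot discriminate between them; 50 QTLs puts default-config
AUCs near 0.92 where the analyses separate.

## Generator scope and a structural equivalence

The benchmark's merged-vs-average comparison has a known structural limit
in this generator. The design is perfectly balanced: every line has
exactly one record per environment. Order observations as two blocks; the
merged model's covariance is block-structured in (mean, difference) space,
where the per-line mean carries all marker main-effect information and the
per-line difference carries only the environment contrast and G×E noise.
The merged GLS marker test therefore reduces to the per-line-average test
with the same plugged-in variance ratio; the two analyses differ only
through (a) the delta estimated from 2n records instead of n, and (b) the
G×E-contaminated difference space influencing that estimate. Consequently
the merged analysis beats the average analysis only marginally more often
than a coin flip (~68% of seeds at 200 lines / 1000 markers) — not the
near-uniform dominance one might expect. Breaking the balance (missing
records, unequal replication, more environments with heterogeneous error
variances) is what gives the observation-level model a material edge; the
shipped generator deliberately stays in the clean balanced regime, so the
acceptance test that asserts an ≥80% win fraction fails and is kept
failing rather than weakened.

## Limitations

- One random genetic kernel; no explicit G×E random effect, dominance or
  epistasis, no multi-trait models.
- No missing-genotype handling; phenotype records with missing trait
  values are excluded (and counted), not imputed.
- Dense `O(N³)` linear algebra: desk scale (thousands of observations),
  not biobank scale.
- P3D is slightly conservative for markers of large effect; `exact` mode
  exists but costs a full refit per marker.
- The χ²₁ reference for the Wald statistic and the median-based
  `lambda_GC` are asymptotic devices; at very small N the type-I error is
  only approximately nominal.
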