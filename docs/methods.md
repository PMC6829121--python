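# Methods

This note documents the models, numerical choices, and limitations behind
`mtcv`. Notation: trait 1 is the focal trait, trait 2 the secondary trait;
subscript `n` ("new") is the test partition, `o` ("old") the training
partition; hats denote estimates.

## Trait model and simulation

Phenotypes are standardized so each trait has unit phenotypic variance on a
GRM with mean diagonal 1; heritabilities are then variances: `g_ii = h_i²`,
`r_ii = 1 − h_i²`, with genetic and residual correlations `ρg`, `ρR` filling
the off-diagonals of the 2×2 matrices `G` and `R`. Trait pairs are drawn from
the matrix-normal model `Y = U + E`, `U ~ MN(0, K, G)`, `E ~ MN(0, I, R)` by
the two-sided Cholesky transform `U = L_K Z_u L_Gᵀ`, `E = Z_e L_Rᵀ`: this is
exact (no eigen-sampling or truncation) and lets the same standard-normal
`Z` matrices be reused across every architecture within a replicate.

**Common random numbers.** All architectures in a grid share the replicate's
`Z_u`, `Z_e`, the partitions, and (for the clone design) the extra residual
draws. Differences between architectures or methods within a replicate are
then driven by the parameters, not by draw-to-draw noise, which sharpens
selection-frequency comparisons considerably. Replicates use independent
spawned seed streams, so results are identical regardless of execution
order or parallelism.

## Synthetic breeding GRM

Real line-breeding programs have strong family structure. The generator
draws family-specific allele frequencies from a Balding–Nichols model with
differentiation `fst` around uniform base frequencies in [0.1, 0.9], samples
diploid dosages per line, and forms the VanRaden GRM
`ZZᵀ / (2Σp(1−p))` from observed frequencies, dropping monomorphic markers.
The matrix is rescaled to mean diagonal 1 (so that "heritability" retains
its proportion-of-variance meaning in the simulations) and jittered so the
smallest eigenvalue is at least 1e-8.

Expected within-family relatedness after rescaling is `2·fst/(1+fst)`; the
default `fst = 0.25` gives ≈ 0.4, matching the relatedness of close-relative
pairs in wheat breeding panels (≈ 0.38 for nearest-relative pairs) and the
calibration band 0.3–0.6 for such populations. Between-family relatedness is
≈ 0. The default study population is 400 lines in 40 families genotyped at
2000 markers — chosen so that a full grid runs in minutes on one CPU.

What the generator does **not** emulate: pedigree depth beyond one level of
family structure, linkage disequilibrium along chromosomes, selection-induced
relatedness gradients, allele-frequency spectra of real SNP panels, and
genotype errors. Conclusions from passing tests therefore concern the
mixed-model machinery and the estimator biases — which depend on `K` only
through `Σc` and relatedness magnitudes — not on any finer population
genetics.

## REML

Both mixed models have an intercept as the only fixed effect and a known
`K`. With `K = QΛQᵀ`, rotating phenotypes by `Qᵀ` makes lines independent:

* **Univariate.** The intercept and total variance are profiled out
  analytically, leaving a 1-D REML profile in `h²`, minimized by a 41-point
  grid scan plus bounded local polish (the profile is cheap and occasionally
  multimodal). Boundary estimates — including the flat-profile case `K = I`,
  where any `h²` is optimal — are returned with a `boundary` flag.
* **Bivariate.** The six (co)variance parameters are optimized on the
  Cholesky-log scale (`G = LLᵀ`, `L = [[eᵃ,0],[b,eᶜ]]`), which keeps both
  matrices positive definite by construction; each objective evaluation
  costs O(n) analytic 2×2 operations. L-BFGS-B runs from the moment start
  `G₀ = R₀ = ½·cov(Y)` with a diagonal-only restart on failure; relative
  log-likelihood tolerance 1e-10, parameter bounds caging variances in
  [e⁻²⁴, e¹²]. Non-convergence is flagged on the fit, never raised, so a
  grid run records the replicate as missing rather than aborting — and
  flagged fits are *included* by default, because estimation noise in
  (ĝ12, r̂12) is part of the phenomenon being studied (it is what degrades
  CV1 at weak correlations).

BLUPs come from the same rotated representation; `blup_with_fixed_components`
exposes the identical linear algebra at user-supplied (G, R) for oracle runs
with the true covariances.

## Predictors and the conditional-covariance convention

The CV2 predictor and its bias correction involve the conditional genetic
covariance of the test lines given the training lines. Throughout, this is
the Schur complement `Σc = Knn − Kno Koo⁻¹ Kon`, equivalently
`[(K⁻¹)nn]⁻¹`. Under this convention the two-step CV2 predictor is exactly
the multivariate-normal conditional mean `E[u_n1 | u_o = û_o, y_n2]`, and
`Vc = g22 Σc + r22 I` is exactly `var(y_n2 | u_o)`; both identities are
enforced by brute-force dense-algebra oracle tests. All solves go through
Cholesky factorizations of `Koo` and the symmetrized `Vc`; no full `K` is
ever inverted.

The two-step structure (train on the training partition only, then combine
with `y_n2`) is deliberate: no test-line data enter model training, matching
how the predictor would be deployed in a breeding program. A one-step joint
fit including `y_n2` would be slightly more accurate and is out of scope.

## Accuracy estimators

* **1/h rescaling.** Under the model `cor(û, y) = cor(û, u)·h`, so
  phenotype-validated correlations are divided by `h1 = √h1²` to land on the
  genetic-accuracy scale. A config switch (`correction: h2`) divides by
  `h1²` instead for sensitivity analysis; the choice cancels out of any
  between-method comparison because the same factor is applied to every
  method.
* **Semi-parametric bias.** The CV2 predictor's second term regresses on
  `y_n2`, whose residual covaries with the validation residual `e_n1`
  (per-line covariance `r12`). Propagating this through the predictor gives
  the cross-covariance `g12·r12·Σc Vc⁻¹`, hence an expected excess sample
  covariance `g12·r12·tr(S Σc Vc⁻¹)/(n−1)` with centering `S = I − 11ᵀ/n` —
  derived here from first principles because published renderings of the
  trace term are ambiguous (a trailing `Knn` factor of unclear role). The
  derivation is *required* to pass a Monte-Carlo oracle: with the true G and
  R, the analytic term matches the mean of
  `cov(û3, y_n1) − cov(û3, u_n1)` over thousands of simulated replicates
  within Monte-Carlo error (the covariance-scale identity is exact in
  expectation; the correlation-scale version inherits a small ratio
  curvature of order 1/n_test). The correction applied in practice divides
  by the sample standard deviations of `û3` and `y_n1` and uses the
  *training-fit* `ĝ12, r̂12`, so its real-data quality degrades exactly as
  the covariance estimates do.
* **Parametric.** The prediction is treated as a selection index `I`; index
  accuracy is `ρg(I,y)·h_I`. Both parameters are re-estimated by a bivariate
  REML fit on the *validation* lines only (hence the 50:50 split for this
  design — both sides need enough lines to estimate a genetic correlation).
  Indexes with no detectable genetic variance return 0; failed validation
  fits return missing.
* **CV2\*.** Clone design: each test line gets two independent phenotype
  copies with residual variance `2R` (a clone plot carries half the data of
  a line mean); copy A's secondary trait drives the prediction, copy B's
  focal trait validates it. The rescaling uses the inflated phenotypic
  variance `h1² + 2r11` so the corrected scale stays comparable; the same
  factor is applied to the single-trait comparator, scored against the same
  `y_x1`, so model comparison is unaffected. Nearest-relative design:
  after drawing the test set, each test line is greedily assigned its most
  related remaining line (`argmax_j K_ij`) as surrogate, processing test
  lines in descending order of best available relatedness (ties to the
  lowest index) so strong matches are not squandered; surrogates are removed
  from training (80:10:10).
* **Full-data EBV predictand.** Implemented solely to demonstrate its
  invalidity: scoring against BLUPs from a fit to the complete data reuses
  training phenotypes inside the predictand and inflates every method's
  estimated accuracy, worst for CV2. It is off by default
  (`include_ebv: false`).

Pearson correlations use (n−1) normalization throughout; zero-variance
inputs yield missing values with a logged warning.

## Experiment design defaults

Test fractions per design: 90:10 for naive and clone CV2\*, 50:50 for
parametric, 80:10:10 for nearest-relative. The shipped architecture grid is
`h1² = 0.2`, `h2² ∈ {0.2, 0.6}`, `ρg ∈ {0, 0.3, 0.6}`,
`ρR ∈ {−0.6, …, 0.6}` (42 combinations). Selection frequencies declare the
per-architecture best method by mean true accuracy; exact ties in estimated
accuracy count 0.5, and replicates missing either estimate leave the
denominator. The default profile (400 lines, 200 replicates) keeps a full
grid within desk-scale runtimes; a larger population is one config entry
away.

## Known limitations

* The desk-scale population halves the validation-set size relative to a
  ~800-line program; per-replicate naive estimates are Pearson correlations
  on ~40 lines, whose sampling noise (sd ≈ 0.16) softens selection-frequency
  extremes relative to larger panels. Mean accuracies and bias signs are
  unaffected; the same code at 800 lines sharpens the selection results.
* Two traits only; no genotype-by-environment structure, non-Gaussian
  residuals, or covariates beyond the intercept.
* The semi-parametric correction is derived for linear mixed-model
  predictors with a fixed kernel; it does not transfer to nonlinear
  predictors.
* REML convergence tolerances are this package's own; small-sample component
  estimates can differ in the last digits from other REML implementations.
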