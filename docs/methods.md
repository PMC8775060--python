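# Methods

## Model

Given genotype dosages `X ∈ ℝ^{n×p}`, an outcome `y` and the linear
model `y = Xβ + ε` with `ε ~ N(0, σ²Iₙ)`, the Lasso criterion
`‖y − Xβ‖² + 2λ‖β‖₁` can be rewritten in terms of the SNP-wise
correlations `r = Xᵀy` as

    L(β) = yᵀy + (1−s)·βᵀ XrᵀXr β − 2βᵀr + s·βᵀβ + 2λ‖β‖₁ ,

where `Xr` supplies the LD estimate and `s` mixes in a ridge term that
makes the solution unique. The two inputs `(r, XrᵀXr)` can come either
from individual-level data (`Xr = X`, `r = Xᵀy`) or from GWAS summary
statistics plus an external reference panel, which is what makes the
formulation attractive for risk-score work: the quadratic, linear and
penalty terms never require subject-level outcome data once `r` is
known.

## Nesterov smoothing with the entropy prox-function

A piecewise-affine convex `f(z) = maxᵢ (A[z,1]ᵀ)ᵢ` is smoothed by
maximizing `⟨A[z,1]ᵀ, w⟩ − μρ(w)` over the unit simplex. With the
entropy prox-function `ρ` this has the closed form

    fμ(z) = μ·log( (1/k) Σᵢ exp((A[z,1]ᵀ)ᵢ / μ) ),

uniformly within `μ·log k` of `f`. The absolute value is the `k = 2`
case `A = [[−1,0],[1,0]]`, giving

    fμ(z) = μ·log(½e^{−z/μ} + ½e^{z/μ}),   fμ′(z) = tanh(z/μ),

and the penalty substitution changes the objective by at most

    0 ≤ L(β) − Lμ(β) ≤ 2λpμ·log 2        for every β.

Consequences used throughout: `Lμ` is strictly convex for `s > 0`
(unique minimum), has a closed-form gradient

    ∇Lμ = 2(1−s)·XrᵀXr β − 2r + 2sβ + 2λ·tanh(β/μ)  (componentwise),

and its minimizer's exact-objective value is within the bound of the
exact Lassosum minimum — an a-priori, user-controllable error that
shrinks linearly in `μ`.

The generic entropy-smoothing machinery (`SmoothingSpec`,
`piecewise_max`, `entropy_smooth`) is retained as an independently
testable oracle; the fitting path uses only the specialized
absolute-value forms.

## Numerical choices

- **Overflow.** `e^{z/μ}` overflows for `z/μ ≳ 700`, which `μ = 0.1`
  reaches at moderate effect sizes. The smoothed absolute value is
  evaluated in the folded form `|z| + μ·log((1 + e^{−2|z|/μ})/2)`, the
  generic case through a log-sum-exp, and the derivative as `tanh`,
  which saturates without overflow. Safe up to `|z|/μ ~ 1e4` and beyond.
- **μ = 0.** The closed form is undefined there; the exact unsmoothed
  function is returned, matching the limit.
- **Optimizer.** L-BFGS (scipy's implementation) with the analytic
  gradient; any line-search quasi-Newton method meeting the
  objective+gradient contract would do. Convergence is declared when the
  gradient sup-norm is ≤ `grad_tol` (default 1e-6); `ftol` is tightened
  to 1e-18 so the gradient criterion dominates; `max_iter` defaults to
  10⁴ and exhaustion returns an unconverged flag, never an exception.
  Initialization is β₀ = 0 — feasible, cheap, and immaterial because the
  objective is strictly convex.
- **LD is matrix-free.** The quadratic is computed as `‖Xrβ‖²` (or via a
  user operator `v ↦ XrᵀXr v`); the p×p LD matrix is never formed.
- **Standardization.** Dosage columns are centered and scaled to unit L2
  norm, so `diag(XrᵀXr) = 1` and correlations and LD live on the same
  scale. Training constants are stored and reused for prediction —
  anything else leaks validation information. Zero-variance columns are
  dropped with a warning (the returned object records the kept-column
  map).
- **Default parameters.** `λ = 2⁻³` (fixed once, chosen so estimates are
  neither dense nor empty), `s = 0.5`, `μ = 0.1`. No λ-path or
  cross-validation: the three parameters are user-fixed.

## Integrated risk models

Covariates are handled by plain linear residualization, for binary
outcomes too — predictions are real-valued scores and AUC is rank-based,
so calibration is immaterial. The pipeline is: OLS of `y` on `[1, Z]`;
recompute `r` from the residuals; fit the smoothed Lassosum with LD from
the standardized study genotypes; predict as
`ŷ = [1,Z]γ̂ + X_std·β̂`.

One design choice deserves emphasis: the residual vector is **scaled to
unit L2 norm** before forming `r = X_stdᵀu`, and the norm is folded back
into the stored `β̂` afterwards. Raw residual correlations scale with
`‖resid‖` (order √n), which would make the fixed `λ` mean something
different in every dataset and put the individual-level and
summary-statistics modes on incompatible scales. On the unit scale both
modes fit the same correlation-sized problem, and residual-based `r`
(which is otherwise not guaranteed to lie in (−1,1)) behaves; entries
outside the interval are still possible and are counted and warned
about, not rejected, since no principled transformation exists.

In summary-statistics mode, marginal effect sizes are converted by the
t-statistic identity `r = t/√(n−2+t²)`, `t = β/se`, which reproduces the
Pearson correlation of variant and outcome exactly for a simple linear
regression; the conversion is exact on the package's own simulated
statistics and is the natural choice when the GWAS provides `(β, se, n)`.
`yᵀy` is unknown in this mode and set to 0 — it shifts the objective by
a constant and never moves the minimizer.

The smoothed minimizer is dense: near zero the penalty gradient
`2λ·tanh(β/μ) ≈ (2λ/μ)·β` acts like a ridge rather than a threshold, so
unused predictors keep small non-zero coefficients (at `μ = 0.1` and the
default `λ`, null effects settle around the null scale `1/√n` of the
correlations rather than at exactly zero). `sparsify(β̂, τ)` restores
hard sparsity post hoc by zeroing `|βᵢ| < τ`; choosing τ trades
sparseness against predictive accuracy and is left to the user.

Evaluation metrics: mean of absolute residuals `(1/n)Σ|yᵢ − ŷᵢ|`,
Pearson correlation of predicted and true outcomes, and — for binary
outcomes only — AUC with ties counted ½ (Mann–Whitney convention). The
covariate-only baseline (`fit_epi_only`) is the same pipeline with
`β̂ = 0`.

## Data handling

PLINK 1 bed/bim/fam triples are read and written directly (two-bit
SNP-major codec; 00 → two copies of the first bim allele, 10 → one,
11 → zero, 01 → missing). Missing calls are imputed to the variant mean,
which preserves column means and is standard in PRS practice. Variant
keys are `chromosome:position:sorted-allele-pair` with 1-based
positions. Harmonization matches on chromosome:position, keeps the
effect size when the effect allele equals the panel's counted allele,
flips its sign when the pair is swapped, and drops strand-ambiguous
(A/T, C/G) pairs and allele-set mismatches with counts — dropping is the
conservative default absent allele-frequency information.

## Synthetic cohorts

`simulate_genotypes` draws, per haplotype, latent Gaussian vectors with
block-wise AR(1) correlation `ld_rho^{|i−j|}` (block size 20 by default)
and thresholds them at the MAF quantile; the two haplotype indicators
sum to a {0,1,2} dosage. Per-variant MAFs are uniform on [0.05, 0.5]. An
independent reference panel is drawn from the same process with the same
MAFs, mimicking an external LD reference. `simulate_phenotype` puts
equal-magnitude, random-sign effects (Gaussian optional) on `n_causal`
variance-standardized dosages, scaled so the genetic variance equals
`h2`; noise variance is `1 − h2`; covariates are standard normal with
fixed linear effects; binary endpoints threshold the liability at the
prevalence quantile of its theoretical distribution.
`make_summary_stats` runs the per-variant simple regressions and records
`(β, se, p, n)`.

What this emulates — and what it does not: block AR(1) LD exercises the
LD-dependent quadratic and the reference-vs-study LD mismatch, but it is
not a human LD map; there is no population structure, relatedness,
genotyping error or imputation uncertainty. Passing tests therefore
demonstrate correctness of the machinery and the internal consistency of
the two input modes, not field performance on biobank data.

All generators are reproducible bit-for-bit from a single seed, with
independent named substreams for MAFs, study panel, reference panel and
phenotype so components can be regenerated in any order.

## Problem sizes

The test suite and `scripts/acceptance.py` use desk-scale problems
chosen to make the statistical checks well-powered while keeping runs
fast: cohorts of 1000–1200 samples with 150–200 variants and 10 causal
effects at `h² = 0.5` (half the cohort for training, half held out;
reference panels of 500–600 samples), 10⁴ Monte-Carlo draws for the
deviation-bound check, and 100 random instances for gradient
verification. The heritability-calibration check uses n = 20000, where
the realized genetic variance fraction concentrates within ±0.03 of its
target.

## Known limitations

- Residual-based correlations can leave (−1,1); the package warns and
  proceeds, as no principled transformation exists.
- Dense minimizers: variable selection is only available via post-hoc
  thresholding.
- LD is used exactly (full quadratic); no windowed/block approximation,
  so very large p requires the operator interface.
- Harmonization has no frequency-based resolution of strand-ambiguous
  variants; they are dropped.
- The bed codec supports the standard SNP-major variant (v1.9 files);
  sample-major files are rejected.
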