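# smoothsum

Polygenic risk scores (PRS) and integrated risk models (IRM) fitted by
minimizing a **Nesterov-smoothed Lassosum objective**.

A polygenic risk score predicts disease risk from genotype alone; an
integrated risk model adds epidemiological covariates such as age and
sex. The Lassosum formulation makes the classic Lasso criterion usable
from GWAS *summary statistics*: with SNP-wise outcome correlations
`r = Xᵀy` and linkage-disequilibrium (LD) information from a reference
genotype panel `Xr`, the objective is

```
L(β) = yᵀy + (1−s)·βᵀXrᵀXrβ − 2βᵀr + s·βᵀβ + 2λ‖β‖₁
```

with penalty weight `λ ≥ 0` and a ridge-mixing parameter `s ∈ [0, 1]`
that guarantees a unique solution. The L1 term is non-differentiable, so
`smoothsum` replaces each `|βᵢ|` with its entropy-prox smoothed
surrogate

```
fμ(z) = μ·log(½·e^(−z/μ) + ½·e^(z/μ)),     fμ′(z) = tanh(z/μ),
```

which makes the objective strictly convex with a closed-form gradient,
lets a quasi-Newton method (L-BFGS) minimize it efficiently, and changes
the objective by at most `2λpμ·log 2` uniformly in β — an error bound
known *before* fitting that vanishes as `μ → 0`. Defaults are
`λ = 2⁻³`, `s = 0.5`, `μ = 0.1`.

The package covers both input paths:

- **summary-statistics mode** — a variant effect table (chromosome,
  position, alleles, beta, SE, p-value) harmonized to a reference panel
  (PLINK bed/bim/fam or dosage TSV), effect sizes converted to
  correlations via `r = t/√(n−2+t²)`;
- **individual-level mode** — dosages, outcome and covariates; the
  covariates are regressed out by OLS and the SNP model is fitted to the
  residual correlations.

A synthetic-data module generates LD-structured genotypes (latent
block-AR(1) Gaussians thresholded at MAF quantiles), sparse causal
architectures, continuous or liability-threshold binary outcomes, and
marginal-regression summary statistics, so the whole pipeline is
testable without any external data.

## Worked example

```python
import numpy as np
from smoothsum import (FitConfig, SimulationConfig, deviation_bound, evaluate,
                       fit_irm, predict, simulate_genotypes, simulate_phenotype,
                       train_validation_split)

cfg = SimulationConfig(n=1000, p=200, n_causal=10, h2=0.5,
                       covariate_effects=(0.5, -0.3), seed=7)
study, reference = simulate_genotypes(cfg)
y, Z, true_beta, true_gamma = simulate_phenotype(study, cfg)

train, val = train_validation_split(cfg.n, train_proportion=0.7, seed=1)
model = fit_irm(study.dosages[train], Z[train], y[train], FitConfig())

print(f"smoothing deviation bound: {deviation_bound(0.125, study.p, 0.1):.4f}")
top10 = np.argsort(-np.abs(model.beta_hat))[:10]
hits = np.intersect1d(top10, np.flatnonzero(true_beta)).size
print(f"true causal variants among the 10 largest |beta|: {hits} / 10")
print(f"fitted covariate effects: {np.round(model.gamma_hat[1:], 3)}"
      f"  (truth: {true_gamma})")

scores = predict(model, study.dosages[val], Z[val])
report = evaluate(y[val], scores, "continuous")
print(f"validation MAR: {report.mean_abs_residuals:.3f}")
print(f"validation correlation: {report.correlation:.3f}")
```

prints

```
smoothing deviation bound: 3.4657
true causal variants among the 10 largest |beta|: 10 / 10
fitted covariate effects: [ 0.532 -0.315]  (truth: [ 0.5 -0.3])
validation MAR: 0.630
validation correlation: 0.746
```

The deviation bound says the smoothed optimum's exact-Lassosum objective
value is within 3.47 of the true minimum for this (λ, p, μ) — before any
data are touched. All ten causal variants carry the largest fitted
effects, the covariate coefficients are recovered, and the held-out
correlation of 0.75 is close to the simulation's theoretical ceiling
(√(h² + covariate share) of the outcome variance).

The same workflow is available from the shell:

```sh
smoothsum simulate --n 1000 --p 200 --h2 0.5 --seed 7 --out-prefix out/sim
smoothsum fit --genotypes out/sim_study.bed --phenotype out/sim_phenotype.tsv \
              --train-proportion 0.7 --out-prefix out/model
smoothsum predict --fit-prefix out/model --genotypes out/sim_study.bed \
                  --phenotype out/sim_phenotype.tsv --out out/scores.tsv
smoothsum evaluate --scores out/scores.tsv --phenotype out/sim_phenotype.tsv \
                   --out out/report.json
```

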