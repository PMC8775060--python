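"""Synthetic cohorts: LD-structured genotypes, phenotypes, summary statistics.

The generator emulates the inputs a PRS/IRM analysis consumes without any
external download.  Dosages are built from latent Gaussian haplotypes
with block-wise AR(1) correlation ``ld_rho^|i-j|`` thresholded at
MAF-derived quantiles (two latent draws per sample and variant, summed to
a {0,1,2} dosage), phenotypes follow the linear model
``y = X beta + Z gamma + eps`` with ``eps ~ N(0, sigma^2 I)`` and
``sigma^2`` set from the heritability target, binary endpoints arise by
thresholding the continuous liability at the prevalence quantile, and
marginal per-variant regressions yield GWAS-style summary statistics.

Everything is reproducible bit-for-bit from ``SimulationConfig.seed``;
independent substreams are spawned for genotypes, reference panel,
phenotype and noise so the pieces can be regenerated in any order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .data_io import GenotypePanel, SummaryStatsTable
from .errors import ConfigError

__all__ = [
    "SimulationConfig",
    "simulate_genotypes",
    "simulate_phenotype",
    "make_summary_stats",
]

# non-strand-ambiguous allele pairs to draw variant codings from
_ALLELE_PAIRS = (("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"))


@dataclass(frozen=True)
class SimulationConfig:
    """Generative parameters for a synthetic cohort.

    Defaults describe a desk-scale cohort with realistic block LD
    (adjacent-variant latent correlation 0.5 in blocks of 20), moderately
    common variants (MAF 0.05-0.5), a sparse architecture (10 causal
    variants) and heritability 0.5.
    """

    n: int = 1000
    n_ref: int = 500
    p: int = 200
    maf_range: Tuple[float, float] = (0.05, 0.5)
    ld_rho: float = 0.5
    block_size: int = 20
    n_causal: int = 10
    h2: float = 0.5
    covariate_effects: Tuple[float, ...] = ()
    outcome_type: str = "continuous"
    prevalence: float = 0.2
    effect_dist: str = "fixed"  # "fixed" (equal magnitude, random sign) | "gaussian"
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigError(f"maf_range must lie within (0, 0.5], got {self.maf_range}")
        if not 0.0 <= self.ld_rho < 1.0:
            raise ConfigError(f"ld_rho must lie in [0, 1), got {self.ld_rho}")
        if self.block_size < 1:
            raise ConfigError("block_size must be positive")
        if not 0 <= self.n_causal <= self.p:
            raise ConfigError(f"n_causal must lie in [0, p={self.p}], got {self.n_causal}")
        if not 0.0 <= self.h2 < 1.0 and self.h2 != 1.0:
            raise ConfigError(f"h2 must lie in [0, 1], got {self.h2}")
        if self.outcome_type not in ("continuous", "binary"):
            raise ConfigError(f"unknown outcome_type {self.outcome_type!r}")
        if not 0.0 < self.prevalence < 1.0:
            raise ConfigError("prevalence must lie strictly in (0, 1)")
        if self.effect_dist not in ("fixed", "gaussian"):
            raise ConfigError(f"unknown effect_dist {self.effect_dist!r}")

    def _streams(self):
        """Named independent RNG substreams derived from the single seed."""
        children = np.random.SeedSequence(self.seed).spawn(4)
        return {
            name: np.random.default_rng(child)
            for name, child in zip(("mafs", "study", "ref", "phenotype"), children)
        }


def _latent_block_ar1(rng: np.random.Generator, n: int, p: int,
                      rho: float, block_size: int) -> np.ndarray:
    """Latent N(0,1) matrix with AR(1) correlation rho^|i-j| inside blocks."""
    Z = np.empty((n, p))
    innovations = rng.standard_normal((n, p))
    scale = np.sqrt(1.0 - rho * rho)
    for start in range(0, p, block_size):
        stop = min(start + block_size, p)
        Z[:, start] = innovations[:, start]
        for j in range(start + 1, stop):
            Z[:, j] = rho * Z[:, j - 1] + scale * innovations[:, j]
    return Z


def _panel_from_latents(rng: np.random.Generator, n: int, cfg: SimulationConfig,
                        mafs: np.ndarray, variants: pd.DataFrame,
                        prefix: str) -> GenotypePanel:
    thresholds = sps.norm.ppf(mafs)
    dosage = np.zeros((n, cfg.p))
    for _ in range(2):  # two haplotypes per sample
        Z = _latent_block_ar1(rng, n, cfg.p, cfg.ld_rho, cfg.block_size)
        dosage += (Z < thresholds).astype(float)
    sample_ids = [f"{prefix}{i + 1}" for i in range(n)]
    return GenotypePanel(dosages=dosage, sample_ids=sample_ids,
                         variants=variants.copy())


def simulate_genotypes(
    cfg: SimulationConfig,
) -> Tuple[GenotypePanel, GenotypePanel]:
    """Generate a study panel and an independent reference panel.

    Both panels share variant metadata and MAFs but are drawn from
    independent samples of the same latent process, mimicking a study
    cohort and an external LD reference.
    """
    streams = cfg._streams()
    maf_rng = streams["mafs"]
    mafs = maf_rng.uniform(cfg.maf_range[0], cfg.maf_range[1], size=cfg.p)
    pair_idx = maf_rng.integers(0, len(_ALLELE_PAIRS), size=cfg.p)
    variants = pd.DataFrame(
        {
            "chrom": ["1"] * cfg.p,
            "pos": np.arange(1, cfg.p + 1) * 1000,
            "a1": [_ALLELE_PAIRS[i][0] for i in pair_idx],
            "a2": [_ALLELE_PAIRS[i][1] for i in pair_idx],
        }
    )
    study = _panel_from_latents(streams["study"], cfg.n, cfg, mafs, variants, "S")
    ref = _panel_from_latents(streams["ref"], cfg.n_ref, cfg, mafs, variants, "R")
    return study, ref


def simulate_phenotype(
    panel: GenotypePanel, cfg: SimulationConfig
) -> Tuple[np.ndarray, Optional[np.ndarray], np.ndarray, np.ndarray]:
    """Generate (y, Z, true_beta, true_gamma) for a genotype panel.

    ``n_causal`` effects act on variance-standardized dosages and are
    scaled so the genetic variance equals ``h2``; noise has variance
    ``1 - h2``; covariates are standard normal with the configured linear
    effects on top of the unit-variance genetic-plus-noise liability.
    Binary outcomes threshold the liability at the prevalence quantile of
    its theoretical distribution.
    """
    rng = cfg._streams()["phenotype"]
    n, p = panel.n, panel.p
    X = panel.dosages
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Xs = (X - X.mean(axis=0)) / sd

    true_beta = np.zeros(p)
    if cfg.n_causal > 0 and cfg.h2 > 0:
        causal = rng.choice(p, size=cfg.n_causal, replace=False)
        if cfg.effect_dist == "fixed":
            raw = rng.choice([-1.0, 1.0], size=cfg.n_causal)
        else:
            raw = rng.standard_normal(cfg.n_causal)
        g0 = Xs[:, causal] @ raw
        v0 = float(g0.var())
        if v0 == 0:
            raise ConfigError("degenerate genetic component (zero variance)")
        true_beta[causal] = raw * np.sqrt(cfg.h2 / v0)
    g = Xs @ true_beta

    true_gamma = np.asarray(cfg.covariate_effects, dtype=float)
    c = true_gamma.shape[0]
    Z = rng.standard_normal((n, c)) if c else None
    cov_part = Z @ true_gamma if c else 0.0

    sigma2 = max(1.0 - cfg.h2, 0.0)
    eps = np.sqrt(sigma2) * rng.standard_normal(n) if sigma2 > 0 else 0.0
    liability = g + cov_part + eps

    if cfg.outcome_type == "binary":
        total_var = 1.0 + float(true_gamma @ true_gamma)
        threshold = sps.norm.ppf(1.0 - cfg.prevalence) * np.sqrt(total_var)
        y = (liability > threshold).astype(float)
    else:
        y = np.asarray(liability, dtype=float)
    return y, Z, true_beta, true_gamma


def make_summary_stats(panel: GenotypePanel, y) -> SummaryStatsTable:
    """Marginal GWAS: per-variant simple linear regression of y on dosage.

    Returns effect size, standard error and two-sided t-test p-value per
    variant, with ``n_gwas`` recorded; constant variants are dropped with
    a warning.  The effect allele is the panel's counted allele (a1).
    """
    import warnings

    y = np.asarray(y, dtype=float).reshape(-1)
    X = panel.dosages
    n = y.shape[0]
    if X.shape[0] != n:
        raise ConfigError(f"panel has {X.shape[0]} samples, y has {n}")
    if n < 3:
        raise ConfigError("need at least 3 samples for marginal regression")

    xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sxx = (xc * xc).sum(axis=0)
    syy = float(yc @ yc)
    keep = sxx > 0
    if not np.all(keep):
        warnings.warn(
            f"dropped {int((~keep).sum())} constant variants from summary statistics",
            stacklevel=2,
        )
    sxy = xc.T @ yc
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = sxy / sxx
        sse = np.maximum(syy - beta * sxy, 0.0)
        se = np.sqrt(sse / (n - 2) / sxx)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = beta / se
    tstat[np.isnan(tstat)] = 0.0  # 0/0: no effect, no information
    pval = 2.0 * sps.t.sf(np.abs(tstat), df=n - 2)
    pval = np.clip(pval, np.finfo(float).tiny, 1.0)

    frame = panel.variants.loc[keep, ["chrom", "pos"]].copy()
    frame["effect_allele"] = panel.variants.loc[keep, "a1"].values
    frame["other_allele"] = panel.variants.loc[keep, "a2"].values
    frame["beta"] = beta[keep]
    frame["se"] = se[keep]
    frame["pvalue"] = pval[keep]
    frame["n_gwas"] = n
    return SummaryStatsTable(frame=frame.reset_index(drop=True))
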