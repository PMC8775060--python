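"""Integrated risk models: covariate residualization, fitting, prediction.

An integrated risk model (IRM) augments a polygenic risk score with
epidemiological covariates (age, sex, ...).  The pipeline mirrors how
summary-statistics PRS methods are extended to covariates:

1. ordinary least squares of the outcome on the covariates (with
   intercept) — binary outcomes included, as real-valued scores;
2. SNP-wise correlations recomputed from the residuals;
3. the smoothed Lassosum fit on those correlations with LD taken from the
   (standardized) study genotypes;
4. prediction on new samples as covariate part plus genetic score, using
   the training standardization constants throughout.

Internally the residual vector is scaled to unit L2 norm before forming
the correlations, so that the fitted problem lives on the same
correlation scale as the summary-statistics path and the fixed penalty
``lam = 2**-3`` means the same thing in both modes; the norm is folded
back into the stored SNP effects, leaving the prediction contract
unchanged.  Residual-based correlations are no longer guaranteed to lie
in (-1, 1); entries outside the interval are counted and warned about,
not rejected.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .data_io import (
    GenotypePanel,
    Standardized,
    SummaryStatsTable,
    apply_standardization,
    beta_to_correlation,
    harmonize,
    standardize,
)
from .errors import CollinearityError, ParameterError, ShapeError
from .fit import FitConfig, FitResult, fit_smoothed_lassosum
from .objective import LassosumProblem

__all__ = [
    "IRMFit",
    "PRSFit",
    "EvaluationReport",
    "regress_covariates",
    "residual_correlations",
    "fit_irm",
    "fit_epi_only",
    "fit_prs_from_summary",
    "score_prs",
    "predict",
    "evaluate",
    "sparsify",
    "train_validation_split",
]


@dataclass
class IRMFit:
    """A fitted integrated risk model."""

    gamma_hat: np.ndarray = field(repr=False)  # intercept first
    beta_hat: np.ndarray = field(repr=False)
    standardization: Standardized = field(repr=False)
    variant_ids: List[str]
    outcome_type: str = "continuous"
    covariate_names: List[str] = field(default_factory=list)
    fit_result: Optional[FitResult] = field(default=None, repr=False)
    config: Optional[FitConfig] = None

    def __post_init__(self) -> None:
        if len(self.beta_hat) != len(self.variant_ids):
            raise ShapeError("beta_hat and variant_ids lengths differ")
        if len(self.beta_hat) != len(self.standardization.center):
            raise ShapeError("beta_hat and standardization lengths differ")

    # -- serialization (TSV/JSON, 17 significant digits) --------------------

    def save(self, prefix: Union[str, Path]) -> None:
        prefix = Path(prefix)
        coef = pd.DataFrame(
            {
                "variant_id": self.variant_ids,
                "beta": self.beta_hat,
                "center": self.standardization.center,
                "scale": self.standardization.scale,
                "column": self.standardization.kept,
            }
        )
        coef.to_csv(
            prefix.with_suffix(".coefficients.tsv"),
            sep="\t",
            index=False,
            float_format="%.17g",
        )
        names = ["intercept"] + list(self.covariate_names)
        cov = pd.DataFrame({"name": names, "gamma": self.gamma_hat})
        cov.to_csv(
            prefix.with_suffix(".covariates.tsv"),
            sep="\t",
            index=False,
            float_format="%.17g",
        )
        meta = {"outcome_type": self.outcome_type}
        if self.config is not None:
            meta.update(
                {
                    "mu": self.config.mu,
                    "lam": self.config.lam,
                    "s": self.config.s,
                    "grad_tol": self.config.grad_tol,
                    "max_iter": self.config.max_iter,
                }
            )
        prefix.with_suffix(".meta.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, prefix: Union[str, Path]) -> "IRMFit":
        prefix = Path(prefix)
        coef = pd.read_csv(
            prefix.with_suffix(".coefficients.tsv"), sep="\t",
            float_precision="round_trip",
        )
        cov = pd.read_csv(
            prefix.with_suffix(".covariates.tsv"), sep="\t",
            float_precision="round_trip",
        )
        meta = json.loads(prefix.with_suffix(".meta.json").read_text())
        std = Standardized(
            x=np.empty((0, len(coef))),
            center=coef["center"].to_numpy(float),
            scale=coef["scale"].to_numpy(float),
            kept=coef["column"].to_numpy(int),
        )
        cfg = None
        if "mu" in meta:
            cfg = FitConfig(
                mu=meta["mu"],
                lam=meta["lam"],
                s=meta["s"],
                grad_tol=meta["grad_tol"],
                max_iter=meta["max_iter"],
            )
        return cls(
            gamma_hat=cov["gamma"].to_numpy(float),
            beta_hat=coef["beta"].to_numpy(float),
            standardization=std,
            variant_ids=coef["variant_id"].astype(str).tolist(),
            outcome_type=meta["outcome_type"],
            covariate_names=cov["name"].astype(str).tolist()[1:],
            config=cfg,
        )


@dataclass
class EvaluationReport:
    """Validation metrics: mean absolute residuals, AUC, Pearson correlation."""

    mean_abs_residuals: float
    correlation: Optional[float]
    n_validation: int
    outcome_type: str = "continuous"
    auc: Optional[float] = None

    def to_dict(self) -> dict:
        d = {
            "mean_abs_residuals": self.mean_abs_residuals,
            "correlation": self.correlation,
            "n_validation": self.n_validation,
            "outcome_type": self.outcome_type,
        }
        if self.outcome_type == "binary":
            d["auc"] = self.auc
        return d


# ---------------------------------------------------------------------------
# pipeline stages


def _as_covariate_matrix(Z, n: int) -> Tuple[np.ndarray, List[str]]:
    if Z is None:
        return np.empty((n, 0)), []
    if isinstance(Z, pd.DataFrame):
        return Z.to_numpy(dtype=float), [str(c) for c in Z.columns]
    Z = np.asarray(Z, dtype=float)
    if Z.ndim == 1:
        Z = Z[:, None]
    return Z, [f"covariate_{i}" for i in range(Z.shape[1])]


def regress_covariates(Z, y) -> Tuple[np.ndarray, np.ndarray]:
    """OLS of the outcome on the covariates with an intercept.

    Returns ``(gamma_hat, residuals)`` where ``gamma_hat`` has the
    intercept first.  With no covariates this is the intercept-only fit:
    ``gamma_hat = [mean(y)]`` and mean-centered residuals.  Residuals are
    orthogonal to every covariate column and sum to zero.
    """
    y = np.asarray(y, dtype=float).reshape(-1)
    n = y.shape[0]
    Zm, names = _as_covariate_matrix(Z, n)
    if Zm.shape[0] != n:
        raise ShapeError(f"Z has {Zm.shape[0]} rows, y has {n}")
    c = Zm.shape[1]
    if n <= c + 1:
        raise ShapeError(f"need n > c + 1 samples (n={n}, c={c})")
    design = np.column_stack([np.ones(n), Zm])
    rank = np.linalg.matrix_rank(design)
    if rank < c + 1:
        # locate the offending columns via successive rank checks
        bad = []
        for j in range(c):
            sub = np.column_stack([np.ones(n), Zm[:, : j + 1]])
            if np.linalg.matrix_rank(sub) < j + 2:
                bad.append(names[j] if names else f"covariate_{j}")
        raise CollinearityError(
            f"covariate design is rank deficient; collinear columns: {bad}"
        )
    gamma, *_ = np.linalg.lstsq(design, y, rcond=None)
    residuals = y - design @ gamma
    return gamma, residuals


def residual_correlations(X_std: np.ndarray, residuals: np.ndarray) -> np.ndarray:
    """SNP-wise correlations recomputed from residuals: ``r = X_std^T u``.

    ``X_std`` must have standardized (centered, unit-norm) columns.  For
    residual-based inputs the correlations are not guaranteed to lie in
    (-1, 1); a warning records how many entries fall outside.
    """
    X_std = np.asarray(X_std, dtype=float)
    residuals = np.asarray(residuals, dtype=float).reshape(-1)
    if X_std.shape[0] != residuals.shape[0]:
        raise ShapeError(
            f"X_std has {X_std.shape[0]} rows, residuals has {residuals.shape[0]}"
        )
    r = X_std.T @ residuals
    n_outside = int(np.sum(np.abs(r) >= 1.0))
    if n_outside:
        warnings.warn(
            f"{n_outside} of {r.size} residual-based correlations fall outside "
            "(-1, 1); proceeding without transformation",
            stacklevel=2,
        )
    return r


def _panel_to_matrix(X) -> Tuple[np.ndarray, Optional[List[str]]]:
    if isinstance(X, GenotypePanel):
        return X.dosages, X.variant_keys.tolist()
    X = np.asarray(X, dtype=float)
    return X, None


def fit_irm(
    X,
    Z,
    y,
    cfg: Optional[FitConfig] = None,
    outcome_type: str = "continuous",
) -> IRMFit:
    """Fit an integrated risk model on individual-level data.

    ``X`` is a dosage matrix or :class:`GenotypePanel`, ``Z`` an optional
    covariate matrix/DataFrame, ``y`` the outcome (binary in {0,1} or
    continuous).  Stages: standardize -> regress_covariates ->
    residual_correlations -> fit_smoothed_lassosum -> package.  The fit is
    deterministic given the inputs and config.
    """
    cfg = cfg or FitConfig()
    y = np.asarray(y, dtype=float).reshape(-1)
    Xm, keys = _panel_to_matrix(X)
    if Xm.shape[0] != y.shape[0]:
        raise ShapeError(f"[standardize] X has {Xm.shape[0]} rows, y has {y.shape[0]}")

    try:
        std = standardize(Xm)
    except Exception as err:
        raise type(err)(f"[standardize] {err}") from err
    try:
        gamma, resid = regress_covariates(Z, y)
    except Exception as err:
        raise type(err)(f"[regress_covariates] {err}") from err

    resid_norm = float(np.linalg.norm(resid))
    if resid_norm == 0.0:
        beta = np.zeros(std.x.shape[1])
        fit_res = None
    else:
        u = resid / resid_norm
        try:
            r = residual_correlations(std.x, u)
        except Exception as err:
            raise type(err)(f"[residual_correlations] {err}") from err
        prob = LassosumProblem(ld_source=std.x, r=r, yty=1.0, s=cfg.s, lam=cfg.lam)
        try:
            fit_res = fit_smoothed_lassosum(prob, cfg)
        except Exception as err:
            raise type(err)(f"[fit_smoothed_lassosum] {err}") from err
        # fold the residual norm back so predict works on the outcome scale
        beta = resid_norm * fit_res.beta_hat

    if keys is None:
        keys_all = [f"col{j}" for j in range(Xm.shape[1])]
    else:
        keys_all = keys
    _, cov_names = _as_covariate_matrix(Z, y.shape[0])
    if isinstance(Z, pd.DataFrame):
        cov_names = [str(c) for c in Z.columns]
    return IRMFit(
        gamma_hat=gamma,
        beta_hat=beta,
        standardization=std,
        variant_ids=[keys_all[j] for j in std.kept],
        outcome_type=outcome_type,
        covariate_names=cov_names,
        fit_result=fit_res,
        config=cfg,
    )


def fit_epi_only(X, Z, y, outcome_type: str = "continuous") -> IRMFit:
    """Covariate-only baseline: OLS on the covariates with all SNP effects 0."""
    y = np.asarray(y, dtype=float).reshape(-1)
    Xm, keys = _panel_to_matrix(X)
    std = standardize(Xm)
    gamma, _ = regress_covariates(Z, y)
    _, cov_names = _as_covariate_matrix(Z, y.shape[0])
    if isinstance(Z, pd.DataFrame):
        cov_names = [str(c) for c in Z.columns]
    keys_all = keys if keys is not None else [f"col{j}" for j in range(Xm.shape[1])]
    return IRMFit(
        gamma_hat=gamma,
        beta_hat=np.zeros(std.x.shape[1]),
        standardization=std,
        variant_ids=[keys_all[j] for j in std.kept],
        outcome_type=outcome_type,
        covariate_names=cov_names,
    )


def predict(fit: IRMFit, X_new, Z_new=None) -> np.ndarray:
    """Predict outcomes/scores: ``[1, Z] gamma_hat + X_std beta_hat``.

    New dosages are standardized with the *training* centers and scales.
    When ``X_new`` is a :class:`GenotypePanel` the variant sets must
    match; mismatches raise with the missing/extra keys listed.
    """
    if isinstance(X_new, GenotypePanel):
        new_keys = X_new.variant_keys.tolist()
        lookup = {k: j for j, k in enumerate(new_keys)}
        missing = [k for k in fit.variant_ids if k not in lookup]
        if missing:
            extra = [k for k in new_keys if k not in set(fit.variant_ids)]
            raise ShapeError(
                f"variant mismatch: {len(missing)} fitted variants missing from "
                f"new panel (first few: {missing[:5]}); {len(extra)} extra"
            )
        cols = [lookup[k] for k in fit.variant_ids]
        Xm = X_new.dosages[:, cols]
        X_std = (Xm - fit.standardization.center) / fit.standardization.scale
    else:
        Xm = np.asarray(X_new, dtype=float)
        X_std = apply_standardization(Xm, fit.standardization)

    n = X_std.shape[0]
    Zm, _ = _as_covariate_matrix(Z_new, n)
    if Zm.shape[1] != len(fit.covariate_names):
        raise ShapeError(
            f"fit has {len(fit.covariate_names)} covariates, got {Zm.shape[1]}"
        )
    design = np.column_stack([np.ones(n), Zm])
    return design @ fit.gamma_hat + X_std @ fit.beta_hat


def evaluate(y_true, y_pred, outcome_type: str = "continuous") -> EvaluationReport:
    """Validation metrics for predicted vs. true outcomes.

    Mean absolute residuals always; Pearson correlation (missing with a
    warning when the prediction is constant); AUC only for binary
    outcomes, with tied scores contributing 1/2 (Mann-Whitney).
    """
    y_true = np.asarray(y_true, dtype=float).reshape(-1)
    y_pred = np.asarray(y_pred, dtype=float).reshape(-1)
    if y_true.shape != y_pred.shape:
        raise ShapeError("y_true and y_pred lengths differ")
    if outcome_type not in ("binary", "continuous"):
        raise ParameterError(f"unknown outcome_type {outcome_type!r}")
    mar = float(np.mean(np.abs(y_true - y_pred)))
    if np.ptp(y_pred) == 0.0 or np.ptp(y_true) == 0.0:
        warnings.warn("constant predictions or outcomes: correlation undefined",
                      stacklevel=2)
        corr = None
    else:
        corr = float(np.corrcoef(y_true, y_pred)[0, 1])
    auc = None
    if outcome_type == "binary":
        if not set(np.unique(y_true)) <= {0.0, 1.0}:
            raise ParameterError("binary outcome must take values in {0, 1}")
        if len(np.unique(y_true)) < 2:
            warnings.warn("only one class present: AUC undefined", stacklevel=2)
        else:
            auc = float(roc_auc_score(y_true, y_pred))
    return EvaluationReport(
        mean_abs_residuals=mar,
        correlation=corr,
        n_validation=y_true.shape[0],
        outcome_type=outcome_type,
        auc=auc,
    )


def sparsify(beta_hat, tau: float) -> np.ndarray:
    """Restore sparsity post hoc: zero every entry with ``|beta_i| < tau``."""
    if tau < 0:
        raise ParameterError(f"tau must be non-negative, got {tau}")
    beta_hat = np.asarray(beta_hat, dtype=float)
    return np.where(np.abs(beta_hat) < tau, 0.0, beta_hat)


def train_validation_split(
    n: int, train_proportion: float, seed: int
) -> Tuple[np.ndarray, np.ndarray]:
    """Uniformly random row split, reproducible from a single seed."""
    if not 0.0 < train_proportion < 1.0:
        raise ParameterError("train_proportion must lie strictly in (0, 1)")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = int(round(train_proportion * n))
    n_train = min(max(n_train, 1), n - 1)
    return np.sort(perm[:n_train]), np.sort(perm[n_train:])


# ---------------------------------------------------------------------------
# summary-statistics input path


@dataclass
class PRSFit:
    """A PRS fitted from summary statistics plus a reference LD panel."""

    beta_hat: np.ndarray = field(repr=False)
    variant_ids: List[str]
    standardization: Standardized = field(repr=False)
    fit_result: FitResult = field(repr=False)
    config: FitConfig = None


def fit_prs_from_summary(
    stats: SummaryStatsTable,
    ref_panel: GenotypePanel,
    cfg: Optional[FitConfig] = None,
    n_gwas: Optional[float] = None,
) -> PRSFit:
    """Fit SNP weights from GWAS summary statistics and a reference panel.

    Effects are harmonized to the panel's allele coding, converted to
    SNP-wise correlations via the t-statistic identity, and fitted against
    LD from the standardized reference dosages with ``yty = 0`` (unknown;
    it does not move the minimizer).
    """
    cfg = cfg or FitConfig()
    harm = harmonize(stats, ref_panel)
    tbl = harm.table
    if n_gwas is None:
        if "n_gwas" not in tbl.columns or tbl["n_gwas"].isna().any():
            raise ParameterError(
                "n_gwas must be supplied (column or argument) to convert "
                "effect sizes to correlations"
            )
        n_eff = tbl["n_gwas"].to_numpy(float)
    else:
        n_eff = float(n_gwas)
    r_all = beta_to_correlation(tbl["beta"].to_numpy(float),
                                tbl["se"].to_numpy(float), n_eff)
    std = standardize(ref_panel.dosages[:, harm.kept_index])
    r = np.asarray(r_all)[std.kept]
    prob = LassosumProblem(ld_source=std.x, r=r, yty=0.0, s=cfg.s, lam=cfg.lam)
    fit_res = fit_smoothed_lassosum(prob, cfg)
    keys = ref_panel.variant_keys.tolist()
    kept_keys = [keys[harm.kept_index[j]] for j in std.kept]
    return PRSFit(
        beta_hat=fit_res.beta_hat,
        variant_ids=kept_keys,
        standardization=std,
        fit_result=fit_res,
        config=cfg,
    )


def score_prs(prs: PRSFit, panel: GenotypePanel) -> np.ndarray:
    """Polygenic score of each panel sample under fitted summary weights.

    Dosage columns are matched by variant key and standardized with the
    reference panel's constants before the weighted sum.
    """
    keys = panel.variant_keys.tolist()
    lookup = {k: j for j, k in enumerate(keys)}
    missing = [k for k in prs.variant_ids if k not in lookup]
    if missing:
        raise ShapeError(
            f"variant mismatch: {len(missing)} fitted variants missing from panel "
            f"(first few: {missing[:5]})"
        )
    cols = [lookup[k] for k in prs.variant_ids]
    Xm = panel.dosages[:, cols]
    X_std = (Xm - prs.standardization.center) / prs.standardization.scale
    return X_std @ prs.beta_hat
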