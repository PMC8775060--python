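r"""The Lassosum objective, its smoothed version, gradient, and error bound.

Lassosum rewrites the Lasso criterion :math:`\|y - X\beta\|^2 +
2\lambda\|\beta\|_1` in terms of the SNP-wise correlations
:math:`r = X^\top y` so that it can be evaluated from GWAS summary
statistics plus a reference LD panel :math:`X_r`:

.. math::

    L(\beta) = y^\top y + (1-s)\,\beta^\top X_r^\top X_r \beta
               - 2\beta^\top r + s\,\beta^\top\beta + 2\lambda\|\beta\|_1,

where :math:`s \in [0,1]` mixes the LD quadratic with a ridge term that
guarantees a unique solution, and at :math:`s = 0`, :math:`X_r = X`,
:math:`r = X^\top y` the classic Lasso criterion is recovered exactly.

The smoothed objective :math:`L_\mu` replaces each :math:`|\beta_i|` with
the entropy-prox smoothed absolute value, yielding a gradient in closed
form.  The substitution changes the objective by at most

.. math:: 0 \le L(\beta) - L_\mu(\beta) \le 2\lambda p \mu \log 2

uniformly in :math:`\beta` (see :func:`deviation_bound`), so the smoothing
error is controlled a priori and vanishes as :math:`\mu \to 0`.

The LD quadratic is always computed matrix-free as
:math:`\|X_r\beta\|^2` (or through a user-supplied operator
:math:`v \mapsto X_r^\top X_r v`); the :math:`p \times p` LD matrix is
never materialized.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Union

import numpy as np

from .errors import NumericalError, ParameterError, ShapeError
from .smoothing import smooth_abs, smooth_abs_grad

__all__ = [
    "LassosumProblem",
    "lassosum_objective",
    "smoothed_objective",
    "smoothed_gradient",
    "deviation_bound",
]

LDSource = Union[np.ndarray, Callable[[np.ndarray], np.ndarray]]


@dataclass
class LassosumProblem:
    """Everything the (smoothed) Lassosum objective needs.

    Parameters
    ----------
    ld_source
        Either a standardized reference dosage matrix ``Xr`` of shape
        ``(m, p)`` (columns centered with unit L2 norm, so the implied LD
        matrix ``Xr^T Xr`` has unit diagonal), or a callable implementing
        the operator ``v -> Xr^T (Xr v)``.
    r
        Length-p vector of SNP-wise correlations with the outcome.  When
        built from standardized individual-level data with a unit-norm
        outcome every entry lies in [-1, 1]; residual-based correlations
        may violate this (flagged upstream, not fatal).
    yty
        The outcome sum of squares ``y^T y``; unknown in summary-statistics
        mode, where it defaults to 0.  It shifts the objective by a
        constant and never moves the minimizer.
    s
        Stability/uniqueness regularizer in [0, 1].
    lam
        Lasso penalty weight, >= 0.
    n_ref
        Reference-panel sample count (informational).
    """

    ld_source: LDSource = field(repr=False)
    r: np.ndarray = field(repr=False)
    yty: float = 0.0
    s: float = 0.5
    lam: float = 0.125
    n_ref: Optional[int] = None

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float).reshape(-1)
        if not np.all(np.isfinite(self.r)):
            raise ShapeError("r contains non-finite entries")
        if not 0.0 <= self.s <= 1.0:
            raise ParameterError(f"s must lie in [0, 1], got {self.s}")
        if self.lam < 0:
            raise ParameterError(f"lam must be non-negative, got {self.lam}")
        if self.yty < 0:
            raise ParameterError(f"yty must be non-negative, got {self.yty}")
        if isinstance(self.ld_source, np.ndarray):
            if self.ld_source.ndim != 2 or self.ld_source.shape[1] != self.p:
                raise ShapeError(
                    f"ld_source matrix has shape {self.ld_source.shape}, "
                    f"expected (m, {self.p})"
                )
            if self.n_ref is None:
                self.n_ref = self.ld_source.shape[0]

    @property
    def p(self) -> int:
        """Variant count."""
        return self.r.shape[0]

    def with_params(self, *, s: float, lam: float) -> "LassosumProblem":
        """A copy of the problem with the regularization parameters replaced."""
        return replace(self, s=s, lam=lam)

    def ld_matvec(self, beta: np.ndarray) -> np.ndarray:
        """``Xr^T (Xr beta)``, matrix-free."""
        if callable(self.ld_source):
            return np.asarray(self.ld_source(beta), dtype=float).reshape(-1)
        return self.ld_source.T @ (self.ld_source @ beta)

    def ld_quadform(self, beta: np.ndarray) -> float:
        """``beta^T Xr^T Xr beta``, as a squared norm when Xr is a matrix."""
        if callable(self.ld_source):
            return float(beta @ self.ld_source(beta))
        xb = self.ld_source @ beta
        return float(xb @ xb)


def _check_beta(beta, prob: LassosumProblem) -> np.ndarray:
    beta = np.asarray(beta, dtype=float).reshape(-1)
    if beta.shape[0] != prob.p:
        raise ShapeError(f"beta has length {beta.shape[0]}, expected p = {prob.p}")
    if not np.all(np.isfinite(beta)):
        raise NumericalError("beta contains non-finite entries")
    return beta


def _assemble(prob: LassosumProblem, beta: np.ndarray, penalty: float) -> float:
    terms = {
        "yty": prob.yty,
        "LD quadratic": (1.0 - prob.s) * prob.ld_quadform(beta),
        "correlation": -2.0 * float(beta @ prob.r),
        "ridge": prob.s * float(beta @ beta),
        "penalty": penalty,
    }
    for name, value in terms.items():
        if not np.isfinite(value):
            raise NumericalError(f"non-finite objective: the {name} term overflowed")
    return float(sum(terms.values()))


def lassosum_objective(beta, prob: LassosumProblem) -> float:
    """The exact (unsmoothed) Lassosum objective L(beta)."""
    beta = _check_beta(beta, prob)
    return _assemble(prob, beta, 2.0 * prob.lam * float(np.sum(np.abs(beta))))


def smoothed_objective(beta, prob: LassosumProblem, mu: float) -> float:
    """The smoothed Lassosum objective L_mu(beta), mu > 0."""
    if mu <= 0:
        raise ParameterError(f"mu must be positive, got {mu}")
    beta = _check_beta(beta, prob)
    penalty = 2.0 * prob.lam * float(np.sum(smooth_abs(beta, mu)))
    return _assemble(prob, beta, penalty)


def smoothed_gradient(beta, prob: LassosumProblem, mu: float) -> np.ndarray:
    """Closed-form gradient of :func:`smoothed_objective`.

    Component i is ``2(1-s)(Xr^T Xr beta)_i - 2 r_i + 2 s beta_i
    + 2 lam tanh(beta_i / mu)``, computed matrix-free.
    """
    if mu <= 0:
        raise ParameterError(f"mu must be positive, got {mu}")
    beta = _check_beta(beta, prob)
    grad = (
        2.0 * (1.0 - prob.s) * prob.ld_matvec(beta)
        - 2.0 * prob.r
        + 2.0 * prob.s * beta
        + 2.0 * prob.lam * smooth_abs_grad(beta, mu)
    )
    if not np.all(np.isfinite(grad)):
        raise NumericalError("non-finite gradient: the LD term overflowed")
    return grad


def deviation_bound(lam: float, p: int, mu: float) -> float:
    """A-priori uniform bound on L - L_mu: ``2 * lam * p * mu * log 2``.

    Valid for every beta; tightening mu tightens the fit of the smoothed
    solution to the exact Lassosum optimum at the same rate.
    """
    if lam < 0:
        raise ParameterError(f"lam must be non-negative, got {lam}")
    if p < 1:
        raise ParameterError(f"p must be a positive integer, got {p}")
    if mu <= 0:
        raise ParameterError(f"mu must be positive, got {mu}")
    return 2.0 * lam * p * mu * float(np.log(2.0))
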