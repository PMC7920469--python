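"""Gaussian knockoff construction and sampling.

A knockoff copy ``X_tilde`` of a design ``X`` with rows x_i ~ N(0, Sigma) is
drawn conditionally on X as

    x_tilde_i | x_i ~ N(mu_i, V),
    mu_i = x_i - x_i Sigma^{-1} diag{a},
    V    = 2 diag{a} - diag{a} Sigma^{-1} diag{a},

where the decorrelation vector ``a`` (entrywise positive) is chosen so that V
is positive definite.  Jointly, rows of [X X_tilde] are Gaussian with
covariance

    G = [[Sigma, Sigma - diag{a}], [Sigma - diag{a}, Sigma]],

which makes originals and knockoffs exchangeable for null variables: the key
structural property behind FDR-calibrated selection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numpy.typing import ArrayLike, NDArray
from sklearn.covariance import LedoitWolf

__all__ = [
    "DefinitenessError",
    "KnockoffModel",
    "compute_s_vector",
    "build_knockoff_model",
    "sample_knockoffs",
    "estimate_covariance",
]

#: eigenvalue floor below which a symmetric matrix is treated as non-PD
PD_TOL = 1e-8

#: relative shrink applied to the equicorrelated s-vector for strict definiteness
EQUI_SLACK = 1e-6


class DefinitenessError(ValueError):
    """A matrix required to be positive definite is not."""


def _symmetrize(m: NDArray) -> NDArray:
    return (m + m.T) / 2.0


def _check_pd(sigma: NDArray, name: str = "sigma") -> NDArray:
    sigma = _symmetrize(np.asarray(sigma, dtype=float))
    if sigma.ndim != 2 or sigma.shape[0] != sigma.shape[1]:
        raise ValueError(f"{name} must be a square matrix, got shape {sigma.shape}")
    eigmin = float(np.linalg.eigvalsh(sigma)[0])
    if eigmin < PD_TOL:
        raise DefinitenessError(
            f"{name} is not positive definite: minimum eigenvalue {eigmin:.3e} "
            f"< tolerance {PD_TOL:.0e}"
        )
    return sigma


@dataclass(frozen=True)
class KnockoffModel:
    """Conditional law of the knockoff rows given the originals.

    Attributes
    ----------
    sigma : (p, p) ndarray
        Covariance of the original rows (assumed mean-zero Gaussian).
    a : (p,) ndarray
        Positive decorrelation vector; ``sigma - diag(a)`` is the
        cross-covariance between originals and knockoffs.
    cond_shift : (p, p) ndarray
        ``Sigma^{-1} diag(a)``; the conditional mean of a knockoff row is
        ``x_i - x_i @ cond_shift``.
    cond_cov : (p, p) ndarray
        ``V = 2 diag(a) - diag(a) Sigma^{-1} diag(a)``, the conditional
        covariance, positive definite.
    """

    sigma: NDArray
    a: NDArray
    cond_shift: NDArray
    cond_cov: NDArray
    _chol: NDArray = field(repr=False, default=None)

    @property
    def p(self) -> int:
        return self.sigma.shape[0]

    def joint_covariance(self) -> NDArray:
        """Covariance G of a row of the augmented design [X X_tilde]."""
        cross = self.sigma - np.diag(self.a)
        return np.block([[self.sigma, cross], [cross, self.sigma]])


def compute_s_vector(sigma: ArrayLike, method: str = "equi") -> NDArray:
    """Choose the decorrelation vector ``a`` for a covariance ``sigma``.

    ``"equi"`` uses the closed-form equicorrelated choice
    ``a_j = min(2*lambda_min(sigma), min_j sigma_jj)`` shrunk by a small slack
    so that V stays strictly positive definite.  ``"sdp"`` solves the
    semidefinite program maximizing ``sum(a)`` subject to the joint covariance
    being PSD; it requires a convex solver and falls back to ``"equi"`` with a
    warning when none is available.
    """
    sigma = _check_pd(sigma)
    if method == "equi":
        lam_min = float(np.linalg.eigvalsh(sigma)[0])
        val = min(2.0 * lam_min, float(np.min(np.diag(sigma)))) * (1.0 - EQUI_SLACK)
        return np.full(sigma.shape[0], val)
    if method == "sdp":
        try:
            return _sdp_s_vector(sigma)
        except ImportError:
            warnings.warn(
                "no convex solver available for method='sdp'; "
                "falling back to the equicorrelated s-vector",
                RuntimeWarning,
                stacklevel=2,
            )
            return compute_s_vector(sigma, method="equi")
    raise ValueError(f"unknown s-vector method {method!r}; use 'equi' or 'sdp'")


def _sdp_s_vector(sigma: NDArray) -> NDArray:
    """Full SDP s-vector: maximize sum(a) s.t. 0 <= a, 2*Sigma - diag(a) PSD."""
    import cvxpy as cp  # optional; not a declared dependency

    p = sigma.shape[0]
    a = cp.Variable(p)
    constraints = [a >= 0, a <= np.diag(sigma), 2 * sigma - cp.diag(a) >> 0]
    prob = cp.Problem(cp.Maximize(cp.sum(a)), constraints)
    prob.solve()
    if a.value is None:
        raise DefinitenessError("SDP for the s-vector did not converge")
    # shrink away from the PSD boundary
    return np.clip(a.value, 0.0, None) * (1.0 - EQUI_SLACK) + PD_TOL


def build_knockoff_model(sigma: ArrayLike, a: ArrayLike) -> KnockoffModel:
    """Assemble the conditional sampling law from ``sigma`` and ``a``.

    Raises
    ------
    DefinitenessError
        If ``sigma`` or the implied conditional covariance V is not positive
        definite (the error names V's minimum eigenvalue).
    ValueError
        If ``a`` has non-positive entries or the wrong length.
    """
    sigma = _check_pd(sigma)
    a = np.asarray(a, dtype=float)
    p = sigma.shape[0]
    if a.shape != (p,):
        raise ValueError(f"a must have shape ({p},), got {a.shape}")
    if np.any(a <= 0):
        raise ValueError("all entries of the decorrelation vector a must be > 0")
    diag_a = np.diag(a)
    cond_shift = np.linalg.solve(sigma, diag_a)  # Sigma^{-1} diag(a)
    cond_cov = _symmetrize(2.0 * diag_a - diag_a @ cond_shift)
    eigmin = float(np.linalg.eigvalsh(cond_cov)[0])
    if eigmin < PD_TOL:
        raise DefinitenessError(
            f"conditional covariance V is not positive definite "
            f"(minimum eigenvalue {eigmin:.3e}); choose a smaller a"
        )
    chol = np.linalg.cholesky(cond_cov)
    return KnockoffModel(sigma=sigma, a=a, cond_shift=cond_shift,
                         cond_cov=cond_cov, _chol=chol)


def sample_knockoffs(
    X: ArrayLike,
    model: KnockoffModel,
    seed: int | np.random.SeedSequence | np.random.Generator,
) -> NDArray:
    """Draw one knockoff matrix ``X_tilde`` row-conditionally on ``X``.

    Each row is an independent draw from N(x_i - x_i Sigma^{-1} diag{a}, V).
    Deterministic given ``seed``.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.p:
        raise ValueError(
            f"X must be 2-D with {model.p} columns to match the model, "
            f"got shape {X.shape}"
        )
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(X.shape)
    return X - X @ model.cond_shift + noise @ model._chol.T


def estimate_covariance(X: ArrayLike, method: str = "shrinkage") -> NDArray:
    """Estimate the row covariance of ``X``.

    ``"empirical"`` is the usual sample covariance (may be singular when
    p >= n).  ``"shrinkage"`` is Ledoit-Wolf analytic shrinkage toward a
    scaled identity, strictly positive definite even when p >= n.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("covariance estimation needs a 2-D X with n >= 2 rows")
    if method == "empirical":
        return _symmetrize(np.cov(X, rowvar=False, ddof=1))
    if method == "shrinkage":
        lw = LedoitWolf(assume_centered=False).fit(X)
        return _symmetrize(lw.covariance_)
    raise ValueError(f"unknown covariance method {method!r}; use 'empirical' or 'shrinkage'")
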