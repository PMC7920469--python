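"""Regularization-path entry statistics and the signed-max knockoff statistic.

For the augmented design [X X_tilde] the entry value Z_j of variable j is the
largest penalty tau at which its coefficient is nonzero in the l1-penalized
fit — "how early" the variable enters the path.  Originals and knockoffs are
then compared through

    W_j = max(Z_j, Z_tilde_j) * sign(Z_j - Z_tilde_j),

so large positive W_j means the original entered the path well before its
knockoff.  For null variables the sign of W_j is a fair coin, which is what
the selection thresholds exploit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.typing import ArrayLike, NDArray
from sklearn.linear_model import LogisticRegression, lars_path

__all__ = [
    "KnockoffStatistics",
    "lasso_entry_times",
    "logistic_entry_times",
    "signed_max_statistic",
    "compute_statistics",
]

#: a path coefficient is "nonzero" above this magnitude
COEF_TOL = 1e-8

#: span of the logistic grid: tau_max down to tau_max * GRID_RATIO
GRID_RATIO = 1e-3


@dataclass(frozen=True)
class KnockoffStatistics:
    """Per-variable entry values and signed-max statistics.

    ``Z`` / ``Z_tilde`` are the nonnegative path-entry penalty levels of the
    original / knockoff copies; ``W`` is the signed-max comparison.  The
    ``lambda_grid`` records the descending penalty levels examined (path
    knots for the linear loss, the log-spaced grid for the logistic loss).
    """

    Z: NDArray
    Z_tilde: NDArray
    W: NDArray
    loss: str
    lambda_grid: NDArray


def _check_augmented(X, X_tilde, y):
    X = np.asarray(X, dtype=float)
    X_tilde = np.asarray(X_tilde, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.shape != X_tilde.shape:
        raise ValueError(f"X {X.shape} and X_tilde {X_tilde.shape} must have equal shape")
    if X.shape[0] != y.shape[0]:
        raise ValueError("X and y disagree on the number of observations")
    if X.shape[0] < 2:
        raise ValueError("need at least 2 observations")
    aug = np.hstack([X, X_tilde])
    if np.any(aug.std(axis=0) == 0):
        raise ValueError(
            "augmented design has a zero-variance column; "
            "standardize or drop constant columns first"
        )
    return aug, y


def _first_entry_values(nonzero: NDArray, grid: NDArray) -> NDArray:
    """Entry value per column: grid value at the first index where active."""
    ever = nonzero.any(axis=1)
    first = np.argmax(nonzero, axis=1)
    out = np.zeros(nonzero.shape[0])
    out[ever] = grid[first[ever]]
    return out


def lasso_entry_times(
    X: ArrayLike, X_tilde: ArrayLike, y: ArrayLike
) -> tuple[NDArray, NDArray, NDArray]:
    """Exact lasso path-entry values on the augmented design.

    Uses the piecewise-linear least-angle path, so entry points are the exact
    path knots (no grid artifacts).  Returns ``(Z, Z_tilde, knots)`` where the
    penalty is on the scale of ``max_j |x_j^T y|`` at path start; ``y`` is
    centered and no intercept is fit.

    A variable's entry value is the knot at which it joins the active set —
    the supremum of penalties with a nonzero coefficient — and 0 if it never
    enters.
    """
    aug, y = _check_augmented(X, X_tilde, y)
    n, two_p = aug.shape
    yc = y - y.mean()
    alphas, _, coefs = lars_path(aug, yc, method="lasso")
    nonzero = np.abs(coefs) > COEF_TOL
    # coefficient j is nonzero strictly below its entry knot; the sup of
    # penalties with a nonzero coefficient is the knot itself (one index back)
    ever = nonzero.any(axis=1)
    first = np.argmax(nonzero, axis=1)
    entry = np.zeros(two_p)
    knot = np.maximum(first - 1, 0)
    entry[ever] = n * alphas[knot[ever]]
    p = two_p // 2
    return entry[:p], entry[p:], n * alphas


def logistic_tau_max(aug: NDArray, y: NDArray) -> float:
    """Smallest penalty with an all-zero l1-logistic solution.

    With an unpenalized intercept the null fit has probabilities ybar, so the
    coefficient gradient at zero is X^T (ybar - y) and the solution stays zero
    exactly when tau >= max_j |x_j^T (y - ybar)|.
    """
    return float(np.max(np.abs(aug.T @ (y - y.mean()))))


def logistic_entry_times(
    X: ArrayLike,
    X_tilde: ArrayLike,
    y: ArrayLike,
    lambda_grid: ArrayLike | None = None,
    n_grid: int = 100,
) -> tuple[NDArray, NDArray, NDArray]:
    """Grid path-entry values for l1-penalized logistic regression.

    No exact path exists for the logistic loss, so a descending log-spaced
    grid of ``n_grid`` penalties from tau_max down to tau_max * 1e-3 is swept
    (or ``lambda_grid`` if given).  Z_j is the largest grid penalty at which
    coefficient j is nonzero; 0 if never active on the grid.  The intercept is
    (effectively) unpenalized.
    """
    aug, y = _check_augmented(X, X_tilde, y)
    classes = np.unique(y)
    if not np.all(np.isin(classes, (0.0, 1.0))):
        raise ValueError("logistic outcomes must be binary 0/1")
    if classes.size < 2:
        raise ValueError("logistic outcomes contain a single class; need both 0 and 1")
    if lambda_grid is None:
        tau_max = logistic_tau_max(aug, y)
        grid = np.geomspace(tau_max, tau_max * GRID_RATIO, num=n_grid)
    else:
        grid = np.asarray(lambda_grid, dtype=float)
        if np.any(grid <= 0) or np.any(np.diff(grid) >= 0):
            raise ValueError("lambda_grid must be strictly decreasing and positive")
    two_p = aug.shape[1]
    nonzero = np.zeros((two_p, grid.size), dtype=bool)
    # liblinear: objective C * logloss + ||w||_1, so tau = 1/C; the large
    # intercept_scaling makes the intercept penalty negligible
    clf = LogisticRegression(
        l1_ratio=1.0, solver="liblinear", fit_intercept=True,
        intercept_scaling=100.0, tol=1e-6, max_iter=2000,
    )
    for g, tau in enumerate(grid):
        clf.set_params(C=1.0 / tau)
        clf.fit(aug, y)
        nonzero[:, g] = np.abs(clf.coef_.ravel()) > COEF_TOL
    Z_all = _first_entry_values(nonzero, grid)
    p = two_p // 2
    return Z_all[:p], Z_all[p:], grid


def signed_max_statistic(Z: ArrayLike, Z_tilde: ArrayLike) -> NDArray:
    """W_j = max(Z_j, Z_tilde_j) * sign(Z_j - Z_tilde_j), with sign(0) = 0."""
    Z = np.asarray(Z, dtype=float)
    Z_tilde = np.asarray(Z_tilde, dtype=float)
    if Z.shape != Z_tilde.shape:
        raise ValueError("Z and Z_tilde must have equal length")
    if np.any(Z < 0) or np.any(Z_tilde < 0):
        raise ValueError("entry values must be nonnegative")
    return np.maximum(Z, Z_tilde) * np.sign(Z - Z_tilde)


def compute_statistics(
    X: ArrayLike,
    X_tilde: ArrayLike,
    y: ArrayLike,
    loss: str = "linear",
    n_grid: int = 100,
    lambda_grid: ArrayLike | None = None,
) -> KnockoffStatistics:
    """Entry values and signed-max W for one knockoff draw."""
    if loss == "linear":
        Z, Zt, grid = lasso_entry_times(X, X_tilde, y)
    elif loss == "logistic":
        Z, Zt, grid = logistic_entry_times(X, X_tilde, y, lambda_grid=lambda_grid,
                                           n_grid=n_grid)
    else:
        raise ValueError(f"unknown loss {loss!r}; use 'linear' or 'logistic'")
    return KnockoffStatistics(Z=Z, Z_tilde=Zt, W=signed_max_statistic(Z, Zt),
                              loss=loss, lambda_grid=grid)
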