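"""Gradient kernel dimension reduction (gKDR).

Given predictors X in R^d and a scalar response y, gKDR estimates an
orthonormal matrix B (d x K) such that y is (approximately)
conditionally independent of X given U = X B.  It forms Gaussian Gram
matrices G_X, G_Y and the averaged kernel-gradient matrix

    M_hat = (1/n) sum_i  D_i^T (G_X + n eps I)^{-1} G_Y
                          (G_X + n eps I)^{-1} D_i,

where D_i[a, :] = d k_X(X_a, x)/dx at x = X_i.  For the Gaussian
kernel D_i[a, :] = G_X[a, i] (X_a - X_i) / sigma_x^2, which allows the
whole sum to be contracted into an expression of the form
X^T H X (see ``_averaged_gradient_matrix``), avoiding the O(n^3 d)
naive loop.  B is the matrix of the top-K eigenvectors of M_hat;
everything is deterministic.

In the whole-brain pipeline X is the delay-embedded activity of a
target's presynaptic neurons (plus its own history) and y the target's
next activity value; the estimated U keeps only the few input
combinations informative for prediction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import eigh
from scipy.spatial.distance import pdist

__all__ = ["GkdrConfig", "GkdrProjection", "median_bandwidth",
           "fit_gkdr", "project"]


@dataclass
class GkdrConfig:
    """Hyperparameters of the gKDR fit.

    K : target dimension (3-5 in the whole-brain models).
    sigma_x, sigma_y : Gaussian bandwidths; None selects the median
        heuristic (median pairwise distance over <= 1000 points).
    epsilon : Tikhonov scale for the Gram inverse; None selects
        1e-4 / sqrt(n).
    max_points : fits with more rows are computed on an evenly spaced
        subsample of this size (the Gram matrices are n x n).
    """

    K: int = 3
    sigma_x: float | None = None
    sigma_y: float | None = None
    epsilon: float | None = None
    max_points: int = 1000

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be >= 1")


@dataclass
class GkdrProjection:
    """Orthonormal projection onto the estimated informative subspace."""

    B: np.ndarray                       # d x K, orthonormal columns
    eigenvalues: np.ndarray             # all eigenvalues, nonincreasing
    sigma_x: float
    sigma_y: float
    epsilon: float
    column_index: list[tuple[str, int]] | None = None

    @property
    def K(self) -> int:
        return self.B.shape[1]


def median_bandwidth(X: np.ndarray, max_points: int = 1000) -> float:
    """Median pairwise Euclidean distance over at most ``max_points`` rows."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] > max_points:
        idx = np.linspace(0, X.shape[0] - 1, max_points).astype(int)
        X = X[idx]
    d = pdist(X)
    d = d[d > 0]
    if d.size == 0:
        raise ValueError("all points identical; bandwidth undefined")
    return float(np.median(d))


def _gaussian_gram(X: np.ndarray, sigma: float) -> np.ndarray:
    sq = np.sum(X * X, axis=1)
    D2 = sq[:, None] + sq[None, :] - 2.0 * X @ X.T
    np.maximum(D2, 0.0, out=D2)
    return np.exp(-D2 / (2.0 * sigma ** 2))


def _averaged_gradient_matrix(X, Gx, Gy, eps, sigma_x):
    """Contract (1/n) sum_i D_i^T F D_i into X^T H X.

    With F = (Gx + n eps I)^{-1} Gy (Gx + n eps I)^{-1} and
    D_i[a] = Gx[a, i] (X_a - X_i)/sigma^2, expanding the outer products
    gives H = F.(Gx Gx) - (F Gx).Gx - ((F Gx).Gx)^T + diag(colsum(Gx.(F Gx)))
    (``.`` elementwise), up to the 1/(n sigma^4) factor.
    """
    n = X.shape[0]
    reg = Gx + n * eps * np.eye(n)
    Binv_Gy = np.linalg.solve(reg, Gy)
    F = np.linalg.solve(reg, Binv_Gy.T).T    # (reg^-1 Gy reg^-1), symmetric
    F = 0.5 * (F + F.T)
    P = Gx @ Gx
    Q = F @ Gx
    QG = Q * Gx
    H = F * P - QG - QG.T + np.diag((Gx * Q).sum(axis=0))
    Mhat = X.T @ H @ X / (n * sigma_x ** 4)
    return 0.5 * (Mhat + Mhat.T)


def fit_gkdr(X: np.ndarray, y: np.ndarray,
             config: GkdrConfig | None = None, *,
             column_index=None) -> GkdrProjection:
    """Estimate the informative projection B from (X, y) samples.

    Deterministic: no randomness enters the fit (subsampling for large n
    is evenly spaced).  Raises if the regularized Gram matrix is
    numerically singular, advising a larger epsilon.
    """
    config = config or GkdrConfig()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).reshape(-1, 1)
    n, d = X.shape
    if y.shape[0] != n:
        raise ValueError("X and y must have the same number of rows")
    if n < 10:
        raise ValueError("need at least 10 samples")
    if not (np.isfinite(X).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if config.K > d:
        raise ValueError("K cannot exceed the input dimension")
    if n > config.max_points:
        idx = np.linspace(0, n - 1, config.max_points).astype(int)
        X_fit, y_fit = X[idx], y[idx]
        n = X_fit.shape[0]
    else:
        X_fit, y_fit = X, y
    sigma_x = config.sigma_x or median_bandwidth(X_fit)
    sigma_y = config.sigma_y or median_bandwidth(y_fit)
    eps = config.epsilon if config.epsilon is not None else 1e-4 / np.sqrt(n)
    Gx = _gaussian_gram(X_fit, sigma_x)
    Gy = _gaussian_gram(y_fit, sigma_y)
    try:
        Mhat = _averaged_gradient_matrix(X_fit, Gx, Gy, eps, sigma_x)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "regularized Gram matrix is singular; increase epsilon"
        ) from exc
    evals, evecs = eigh(Mhat)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    B = evecs[:, order[: config.K]]
    # sign convention: largest-magnitude entry of each column positive
    for j in range(B.shape[1]):
        if B[np.argmax(np.abs(B[:, j])), j] < 0:
            B[:, j] = -B[:, j]
    return GkdrProjection(B, evals, sigma_x, sigma_y, eps,
                          column_index=column_index)


def project(X: np.ndarray, proj: GkdrProjection) -> np.ndarray:
    """U = X B, the reduced coordinates."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != proj.B.shape[0]:
        raise ValueError("X column count must equal rows of B")
    return X @ proj.B
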