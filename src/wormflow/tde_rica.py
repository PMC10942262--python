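"""Reconstruction ICA on delay-embedded activity (TDE-RICA).

The method factorises the delay-embedded multi-animal matrix X
(features = neuron x lag, columns = time points pooled across animals)
as X^T ~ W M, where the rows of M are spatiotemporal *motifs* and the
columns of W their time-varying *occurrences* per animal.  W is found by
minimising

    lambda * ||W W^T X^T - X^T||_2^2  +  ||g(W^T X^T)||_1,

with the smooth super-Gaussian contrast g(x) = 1/2 log(cosh 2x); the
reconstruction penalty keeps the decomposition faithful to the data
while the contrast term drives the components toward sparse,
independent occurrences.  M is then W^T X^T.

Missing neurons/animals are handled by a matrix-factorization
extension: the fitted blocks (M, W) are frozen and new blocks
(M_new for unseen neurons, W_new for unseen animals) minimise the
reconstruction cost restricted to observed entries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment, minimize

from .embedding import EmbeddedMatrix

__all__ = [
    "MotifModel",
    "ExtendedMotifModel",
    "contrast_g",
    "rica_cost",
    "fit_rica",
    "complete_by_matrix_factorization",
    "project_onto_motifs",
    "occurrence_crosscorrelation",
    "occurrence_pairs",
    "align_components",
]


@dataclass
class MotifModel:
    """Fitted RICA decomposition of an embedded matrix."""

    M: np.ndarray                  # n x (neurons*k) motifs
    W: np.ndarray                  # (time*samples) x n occurrences
    n: int
    lambda_recon: float
    neuron_order: list[str]
    sample_order: list[str]
    k: int
    tau: int
    col_index: list[tuple[str, int]]
    converged: bool = True
    cost_history: list[float] = field(default_factory=list)

    def occurrences_for(self, sample_id: str) -> np.ndarray:
        rows = [r for r, (sid, _) in enumerate(self.col_index)
                if sid == sample_id]
        return self.W[rows]


@dataclass
class ExtendedMotifModel:
    """RICA blocks plus matrix-factorization completion blocks."""

    M_all: np.ndarray
    W_all: np.ndarray
    neuron_order: list[str]        # RICA neurons first, then new neurons
    sample_order: list[str]        # RICA samples first, then new samples
    n: int
    k: int
    tau: int
    col_index: list[tuple[str, int]]
    from_rica_rows: np.ndarray     # bool per W_all row (time point)
    from_rica_features: np.ndarray  # bool per M_all column (neuron*lag)


def contrast_g(x) -> np.ndarray:
    """Smooth super-Gaussian contrast g(x) = 1/2 log(cosh 2x).

    Computed in an overflow-safe form; even, nonnegative, and
    asymptotically |x| - (log 2)/2.
    """
    ax = np.abs(np.asarray(x, dtype=float))
    # log(cosh 2x) = 2|x| + log((1 + exp(-4|x|)) / 2)
    return 0.5 * (2.0 * ax + np.log1p(np.exp(-4.0 * ax)) - np.log(2.0))


def _contrast_g_prime(x) -> np.ndarray:
    return np.tanh(2.0 * np.asarray(x, dtype=float))


def _as_values(X) -> np.ndarray:
    return X.values if isinstance(X, EmbeddedMatrix) else np.asarray(X, float)


def rica_cost(W: np.ndarray, X, lambda_recon: float) -> float:
    """Evaluate the RICA objective for occurrence matrix ``W``.

    ``X`` is features x time; ``W`` is time x components.
    """
    Xv = _as_values(X)
    W = np.asarray(W, dtype=float)
    if W.shape[0] != Xv.shape[1]:
        raise ValueError("W must have one row per embedded time point")
    A = Xv.T                       # time x features
    M = W.T @ A                    # components x features
    R = W @ M - A
    return float(lambda_recon * np.sum(R * R) + np.sum(contrast_g(M)))


def _cost_grad(Wflat, A, n, lam):
    T = A.shape[0]
    W = Wflat.reshape(T, n)
    M = W.T @ A
    R = W @ M - A
    cost = lam * np.sum(R * R) + np.sum(contrast_g(M))
    gprime = _contrast_g_prime(M)
    grad = lam * (2.0 * R @ M.T + 2.0 * A @ (R.T @ W)) + A @ gprime.T
    return cost, grad.ravel()


def fit_rica(X, n: int, lambda_recon: float = 1.0, seed: int = 0, *,
             max_iter: int = 1000, gtol: float = 1e-6) -> MotifModel:
    """Fit the RICA decomposition by L-BFGS with analytic gradient.

    Deterministic given ``seed`` (Gaussian init of W scaled by
    1/sqrt(rows)).  If the optimizer stops before reaching the gradient
    tolerance the best iterate is returned with ``converged=False``.
    """
    Xv = _as_values(X)
    if not np.isfinite(Xv).all():
        raise ValueError("RICA requires a complete (no missing) matrix")
    A = Xv.T
    T = A.shape[0]
    rng = np.random.default_rng(seed)
    W0 = rng.standard_normal((T, n)) / np.sqrt(T)
    history: list[float] = []

    def cb(wk):
        history.append(_cost_grad(wk, A, n, lambda_recon)[0])

    res = minimize(_cost_grad, W0.ravel(), args=(A, n, lambda_recon),
                   jac=True, method="L-BFGS-B", callback=cb,
                   options={"maxiter": max_iter, "gtol": gtol,
                            "ftol": 1e-12})
    if not res.success and "ABNORMAL" in str(res.message):
        warnings.warn(f"RICA optimizer stopped abnormally: {res.message}")
    W = res.x.reshape(T, n)
    M = W.T @ A
    if isinstance(X, EmbeddedMatrix):
        neuron_order, sample_order = X.neurons, X.samples
        k, tau, col_index = X.k, X.tau, list(X.col_index)
    else:
        neuron_order, sample_order = [], []
        k, tau = 1, 1
        col_index = [("0", t) for t in range(T)]
    return MotifModel(M, W, n, lambda_recon, neuron_order, sample_order,
                      k, tau, col_index, converged=bool(res.success),
                      cost_history=history)


def _masked_cost_grad(theta, W_fix, M_fix, Xt, mask, n, n_new_t, n_new_f):
    """Cost/grad of ||mask*(W_all M_all - X^T)||^2 over (W_new, M_new)."""
    T_old = W_fix.shape[0]
    D_old = M_fix.shape[1]
    W_new = theta[: n_new_t * n].reshape(n_new_t, n)
    M_new = theta[n_new_t * n:].reshape(n, n_new_f)
    W_all = np.vstack([W_fix, W_new]) if n_new_t else W_fix
    M_all = np.hstack([M_fix, M_new]) if n_new_f else M_fix
    R = W_all @ M_all - Xt
    R[~mask] = 0.0
    cost = float(np.sum(R * R))
    gW_all = 2.0 * R @ M_all.T
    gM_all = 2.0 * W_all.T @ R
    gW = gW_all[T_old:] if n_new_t else np.empty((0, n))
    gM = gM_all[:, D_old:] if n_new_f else np.empty((n, 0))
    return cost, np.concatenate([gW.ravel(), gM.ravel()])


def complete_by_matrix_factorization(X_all, model: MotifModel,
                                     seed: int = 0, *,
                                     max_iter: int = 2000,
                                     gtol: float = 1e-8
                                     ) -> ExtendedMotifModel:
    """Extend a fitted motif model over missing neurons / new animals.

    ``X_all`` is an :class:`EmbeddedMatrix` possibly containing NaN.  Its
    neurons/samples are split into the model's (M, W held fixed) and new
    ones; the new blocks minimise the reconstruction cost restricted to
    observed entries, so NaN residuals never contribute.
    """
    if not isinstance(X_all, EmbeddedMatrix):
        raise TypeError("X_all must be an EmbeddedMatrix")
    if X_all.k != model.k or X_all.tau != model.tau:
        raise ValueError("embedding parameters must match the fitted model")
    old_neurons = [nr for nr in model.neuron_order if nr in X_all.neurons]
    if old_neurons != model.neuron_order:
        raise ValueError("X_all must contain every neuron of the model")
    new_neurons = [nr for nr in X_all.neurons if nr not in model.neuron_order]
    old_samples = [s for s in X_all.samples if s in model.sample_order]
    new_samples = [s for s in X_all.samples if s not in model.sample_order]
    if old_samples != model.sample_order:
        raise ValueError("X_all must contain every sample of the model")

    # reorder rows (features) old-neurons-first and columns old-samples-first
    feat_rows = np.concatenate([X_all.rows_for(nr)
                                for nr in old_neurons + new_neurons])
    col_order = np.concatenate(
        [X_all.columns_for(s) for s in old_samples + new_samples]).astype(int)
    Xt = X_all.values[np.ix_(feat_rows, col_order)].T  # time x features
    mask = np.isfinite(Xt)
    col_index = [X_all.col_index[c] for c in col_order]

    D_old = model.M.shape[1]
    T_old = model.W.shape[0]
    n = model.n
    n_new_f = Xt.shape[1] - D_old
    n_new_t = Xt.shape[0] - T_old
    # every new row/column must have at least one observed entry
    if n_new_t and not mask[T_old:].any(axis=1).all():
        raise ValueError("a new time block has zero observed entries")
    if n_new_f and not mask[:, D_old:].any(axis=0).all():
        bad = np.where(~mask[:, D_old:].any(axis=0))[0]
        raise ValueError(f"new features with zero observed entries: {bad}")

    if n_new_f == 0 and n_new_t == 0:
        from_rows = np.ones(T_old, dtype=bool)
        from_feats = np.ones(D_old, dtype=bool)
        return ExtendedMotifModel(model.M.copy(), model.W.copy(),
                                  list(model.neuron_order),
                                  list(model.sample_order), n, model.k,
                                  model.tau, col_index, from_rows, from_feats)

    rng = np.random.default_rng(seed)
    theta0 = np.concatenate([
        (rng.standard_normal((n_new_t, n)) / np.sqrt(max(Xt.shape[0], 1))
         ).ravel(),
        (rng.standard_normal((n, n_new_f)) * 0.01).ravel()])
    res = minimize(_masked_cost_grad, theta0,
                   args=(model.W, model.M, np.nan_to_num(Xt), mask, n,
                         n_new_t, n_new_f),
                   jac=True, method="L-BFGS-B",
                   options={"maxiter": max_iter, "gtol": gtol,
                            "ftol": 1e-15})
    W_new = res.x[: n_new_t * n].reshape(n_new_t, n)
    M_new = res.x[n_new_t * n:].reshape(n, n_new_f)
    M_all = np.hstack([model.M, M_new]) if n_new_f else model.M.copy()
    W_all = np.vstack([model.W, W_new]) if n_new_t else model.W.copy()
    from_rows = np.r_[np.ones(T_old, bool), np.zeros(n_new_t, bool)]
    from_feats = np.r_[np.ones(D_old, bool), np.zeros(n_new_f, bool)]
    return ExtendedMotifModel(M_all, W_all, old_neurons + new_neurons,
                              old_samples + new_samples, n, model.k,
                              model.tau, col_index, from_rows, from_feats)


def project_onto_motifs(X_new, M: np.ndarray):
    """Occurrences of fixed motifs in new data by linear least squares.

    Solves min_W ||W M - X_new^T||^2 in closed form; a rank-deficient M
    yields the minimum-norm solution and sets the returned flag.
    """
    Xv = _as_values(X_new)
    M = np.asarray(M, dtype=float)
    if Xv.shape[0] != M.shape[1]:
        raise ValueError("feature dimensions of X_new and M disagree")
    W, _, rank, _ = np.linalg.lstsq(M.T, Xv, rcond=None)
    rank_deficient = rank < M.shape[0]
    if rank_deficient:
        warnings.warn("motif matrix is rank deficient; "
                      "minimum-norm occurrences returned")
    return W.T, rank_deficient


def _xcorr_pair(a: np.ndarray, b: np.ndarray, max_lag: int) -> np.ndarray:
    """Normalized cross-correlation of two series for lags -L..L.

    Positive lag means ``a`` leads ``b`` (b is shifted back in time).
    Mean-removed, normalized by full-series standard deviations.
    """
    a = a - a.mean()
    b = b - b.mean()
    T = a.size
    denom = a.std() * b.std() * T
    out = np.empty(2 * max_lag + 1)
    for i, lag in enumerate(range(-max_lag, max_lag + 1)):
        if lag >= 0:
            out[i] = np.dot(a[: T - lag], b[lag:]) / denom
        else:
            out[i] = np.dot(a[-lag:], b[: T + lag]) / denom
    return out


def occurrence_crosscorrelation(model_or_W, col_index=None, max_lag: int = 50):
    """Lagged cross-correlations between motif occurrences, per sample.

    Returns ``(lags, per_sample, average)`` where ``per_sample`` maps
    sample id -> (n x n x lags) array and ``average`` is the mean across
    samples.  A zero-variance component yields NaN for its pairs.
    """
    if isinstance(model_or_W, MotifModel):
        W, col_index = model_or_W.W, model_or_W.col_index
    else:
        W = np.asarray(model_or_W, dtype=float)
        if col_index is None:
            col_index = [("0", t) for t in range(W.shape[0])]
    n = W.shape[1]
    lags = np.arange(-max_lag, max_lag + 1)
    samples: dict[str, list[int]] = {}
    for r, (sid, _) in enumerate(col_index):
        samples.setdefault(sid, []).append(r)
    per_sample: dict[str, np.ndarray] = {}
    for sid, rows in samples.items():
        Ws = W[rows]
        C = np.full((n, n, lags.size), np.nan)
        sds = Ws.std(axis=0)
        for i in range(n):
            for j in range(n):
                if sds[i] > 0 and sds[j] > 0:
                    C[i, j] = _xcorr_pair(Ws[:, i], Ws[:, j], max_lag)
        per_sample[sid] = C
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN pairs
        avg = np.nanmean(np.stack(list(per_sample.values())), axis=0)
    return lags, per_sample, avg


def occurrence_pairs(model: MotifModel, comp_a: int, comp_b: int):
    """Paired occurrence trajectories (w_a(t), w_b(t)) per sample.

    The phase-plane view of two components' occurrences, used to compare
    how a pair of motifs co-occurs across animals.
    """
    return {sid: np.column_stack([model.occurrences_for(sid)[:, comp_a],
                                  model.occurrences_for(sid)[:, comp_b]])
            for sid in model.sample_order}


def align_components(M_est: np.ndarray, M_true: np.ndarray):
    """Match estimated to planted components by absolute correlation.

    Hungarian assignment on |corr| between rows; signs fixed so the
    matched correlation is positive.  Returns (permutation, signs,
    matched |corr| per true component).
    """
    M_est = np.asarray(M_est, float)
    M_true = np.asarray(M_true, float)
    ne, nt = M_est.shape[0], M_true.shape[0]
    C = np.zeros((nt, ne))
    for i in range(nt):
        for j in range(ne):
            C[i, j] = np.corrcoef(M_true[i], M_est[j])[0, 1]
    C = np.nan_to_num(C)
    rows, cols = linear_sum_assignment(-np.abs(C))
    perm = np.empty(nt, dtype=int)
    signs = np.empty(nt)
    corr = np.empty(nt)
    for i, j in zip(rows, cols):
        perm[i] = j
        signs[i] = np.sign(C[i, j]) or 1.0
        corr[i] = abs(C[i, j])
    return perm, signs, corr
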