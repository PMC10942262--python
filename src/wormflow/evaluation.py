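"""Model validation, weight-consistency statistics and descriptive analytics.

Validation follows an ensemble protocol: each recording is split into
three contiguous thirds; a model trained on one third is scored on each
third by the mean log-likelihood of the real target activity under the
conditional mixture, and compared against a null in which the
presynaptic (non-self) inputs are permuted along time (100 permutations,
normal approximation, one-sided p).  A model is *qualified* when p <
0.01 on both held-out thirds.  Combined with K in {3,4,5} and thinning
offsets 0..4, this yields 45 models per target and animal; the
consistency of their estimated synaptic weights is assessed with a
rank-sum test of the weight vector against its negation, adjusted by
Benjamini-Hochberg at FDR 0.005.

The analytics half hosts the descriptive measures used on both real and
simulated activity: correlation matrices and their MSE (the
hyperparameter search score), lagged cross-correlations, period-folded
averages and stimulus-frequency Fourier power.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .gmm_predictor import NeuronModel, conditional_batch

__all__ = [
    "CrossValidationResult", "ConsistencyResult",
    "split_thirds", "mean_log_likelihood", "bootstrap_permutation_test",
    "weight_consistency", "benjamini_hochberg", "ensemble_grid",
    "qualify", "correlation_matrix", "correlation_mse",
    "lagged_crosscorrelation", "period_average", "fourier_power",
]


@dataclass
class CrossValidationResult:
    """Scores of models trained/evaluated on the three thirds."""

    target: str
    loglik: np.ndarray       # (3, 3): train third x eval third
    pvalues: np.ndarray      # (3, 3): bootstrap p on each eval third

    def qualified(self, alpha: float = 0.01) -> np.ndarray:
        """Per training third: p < alpha on both held-out thirds."""
        out = np.zeros(3, dtype=bool)
        for tr in range(3):
            held = [ev for ev in range(3) if ev != tr]
            out[tr] = all(self.pvalues[tr, ev] < alpha for ev in held)
        return out


@dataclass
class ConsistencyResult:
    """Weight consistency for one (pre, post) pair."""

    pre: str
    post: str
    weights: np.ndarray
    pvalue: float
    mean_weight: float
    cv: float                 # coefficient of variation across samples
    significant: bool = False


def split_thirds(T: int):
    """Three contiguous, disjoint, covering ranges with sizes within 1."""
    if T < 3:
        raise ValueError("need at least 3 time points")
    sizes = [T // 3 + (1 if i < T % 3 else 0) for i in range(3)]
    edges = np.concatenate([[0], np.cumsum(sizes)])
    return [range(int(edges[i]), int(edges[i + 1])) for i in range(3)]


def mean_log_likelihood(model: NeuronModel, X_eval: np.ndarray,
                        y_eval: np.ndarray) -> float:
    """(1/n) sum_t log p(y(t+dt) | U(t)) under the conditional mixture."""
    X_eval = np.atleast_2d(np.asarray(X_eval, float))
    y = np.asarray(y_eval, float)
    U = X_eval @ model.projection.B
    w, means, variances = conditional_batch(model.gmm, U)
    with np.errstate(divide="ignore"):
        lg = (-0.5 * (y[:, None] - means) ** 2 / variances
              - 0.5 * np.log(2 * np.pi * variances)
              + np.log(np.maximum(w, 1e-300)))
    from scipy.special import logsumexp
    return float(np.mean(logsumexp(lg, axis=1)))


def _self_columns(model: NeuronModel) -> np.ndarray:
    """Boolean mask of embedded columns belonging to the target itself."""
    k = model.kprime
    mask = np.zeros(len(model.pset.explanatory) * k, dtype=bool)
    for pos, neuron in enumerate(model.pset.explanatory):
        if neuron == model.pset.target:
            mask[pos * k: (pos + 1) * k] = True
    return mask


def bootstrap_permutation_test(model: NeuronModel, X_eval: np.ndarray,
                               y_eval: np.ndarray, n_perm: int = 100,
                               seed: int = 0, *,
                               joint: bool = True):
    """One-sided permutation test of predictive value of presynaptic input.

    The non-self embedded channels are permuted along the time axis —
    jointly (one permutation for all channels, preserving their mutual
    structure) by default, or independently per channel — while the
    target's own history stays fixed.  The null scores are summarised by
    a normal fit; returns (p_normal, p_exact, observed, null_scores).
    """
    X_eval = np.atleast_2d(np.asarray(X_eval, float))
    y_eval = np.asarray(y_eval, float)
    rng = np.random.default_rng(seed)
    obs = mean_log_likelihood(model, X_eval, y_eval)
    self_mask = _self_columns(model)
    presyn = ~self_mask
    null = np.empty(n_perm)
    for b in range(n_perm):
        Xp = X_eval.copy()
        if joint:
            perm = rng.permutation(X_eval.shape[0])
            Xp[:, presyn] = X_eval[perm][:, presyn]
        else:
            k = model.kprime
            for pos, neuron in enumerate(model.pset.explanatory):
                if neuron == model.pset.target:
                    continue
                perm = rng.permutation(X_eval.shape[0])
                Xp[:, pos * k: (pos + 1) * k] = \
                    X_eval[perm][:, pos * k: (pos + 1) * k]
        null[b] = mean_log_likelihood(model, Xp, y_eval)
    mu, sd = null.mean(), null.std(ddof=1)
    if sd <= 1e-12 * max(1.0, abs(mu)):     # degenerate null distribution
        p_normal = 0.0 if obs > mu else 1.0
    else:
        p_normal = float(stats.norm.sf((obs - mu) / sd))
    p_exact = float((1 + np.sum(null >= obs)) / (n_perm + 1))
    return p_normal, p_exact, obs, null


def weight_consistency(weights: np.ndarray):
    """Rank-sum test of the weight samples against their negation.

    Returns (p, sign of mean).  A consistently signed set of weights
    separates completely from its mirror image and yields a small p;
    a sign-symmetric set yields p = 1.
    """
    w = np.asarray(weights, float)
    if w.size < 2:
        raise ValueError("need at least 2 qualified weight samples")
    if np.all(w == 0):
        return 1.0, 0.0
    stat, p = stats.ranksums(w, -w)
    return float(p), float(np.sign(w.mean()))


def benjamini_hochberg(pvalues, fdr: float = 0.005) -> np.ndarray:
    """Step-up BH procedure; returns the rejection mask."""
    p = np.asarray(pvalues, float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    reject, *_ = multipletests(p, alpha=fdr, method="fdr_bh")
    return reject


def ensemble_grid(Ks=(3, 4, 5), offsets=(0, 1, 2, 3, 4), n_thirds: int = 3):
    """All (K, offset, training third) combinations: 3 x 5 x 3 = 45."""
    return list(itertools.product(Ks, offsets, range(n_thirds)))


def qualify(cv_results, alpha: float = 0.01):
    """Qualified (K, offset, third) combos from CV results.

    ``cv_results`` maps (K, offset) -> CrossValidationResult; returns the
    list of (K, offset, third) whose double p < alpha criterion holds.
    """
    out = []
    for (K, offset), res in cv_results.items():
        for third, ok in enumerate(res.qualified(alpha)):
            if ok:
                out.append((K, offset, third))
    return out


def correlation_matrix(activity: np.ndarray) -> np.ndarray:
    """Pearson correlations between neuron rows; NaN for constant rows."""
    A = np.atleast_2d(np.asarray(activity, float))
    if A.shape[1] < 2:
        raise ValueError("need at least 2 time points")
    sds = A.std(axis=1)
    C = np.full((A.shape[0], A.shape[0]), np.nan)
    ok = sds > 0
    if ok.any():
        C_ok = np.corrcoef(A[ok])
        C[np.ix_(ok, ok)] = np.atleast_2d(C_ok)
    return C


def correlation_mse(C_sim: np.ndarray, C_ref: np.ndarray) -> float:
    """Mean squared difference over valid off-diagonal entries.

    This is the free-run similarity score used for hyperparameter
    selection: smaller means the simulated pairwise structure is closer
    to the reference.
    """
    C_sim = np.asarray(C_sim, float)
    C_ref = np.asarray(C_ref, float)
    if C_sim.shape != C_ref.shape:
        raise ValueError("correlation matrices must share shape")
    mask = ~np.eye(C_sim.shape[0], dtype=bool)
    mask &= np.isfinite(C_sim) & np.isfinite(C_ref)
    if not mask.any():
        return np.nan
    d = C_sim[mask] - C_ref[mask]
    return float(np.mean(d * d))


def lagged_crosscorrelation(activity: np.ndarray, max_lag: int):
    """Best-|correlation| lag per neuron pair.

    Positive lag means the row neuron leads the column neuron.  Ties are
    broken toward the smallest |lag| (then the negative lag).  Returns
    (best_lag, best_corr) matrices.
    """
    A = np.atleast_2d(np.asarray(activity, float))
    n, T = A.shape
    if max_lag >= T / 2:
        raise ValueError("max_lag must be below half the series length")
    Ac = A - A.mean(axis=1, keepdims=True)
    sds = A.std(axis=1)
    lags = np.arange(-max_lag, max_lag + 1)
    order = np.argsort(np.abs(lags) * 2 + (lags > 0))   # 0, -1, 1, -2, 2...
    best_lag = np.zeros((n, n), dtype=int)
    best_corr = np.full((n, n), np.nan)
    for i in range(n):
        for j in range(n):
            if sds[i] == 0 or sds[j] == 0:
                continue
            cc = np.empty(lags.size)
            for li, lag in enumerate(lags):
                if lag >= 0:
                    cc[li] = np.dot(Ac[i, : T - lag], Ac[j, lag:])
                else:
                    cc[li] = np.dot(Ac[i, -lag:], Ac[j, : T + lag])
            cc /= sds[i] * sds[j] * T
            pick = order[np.argmax(np.abs(cc[order]))]
            best_lag[i, j] = lags[pick]
            best_corr[i, j] = cc[pick]
    return best_lag, best_corr


def period_average(activity: np.ndarray, period_steps: int) -> np.ndarray:
    """Fold the time axis modulo the stimulus period and average.

    Trailing incomplete periods are included (per-phase means over the
    available cycles).
    """
    A = np.atleast_2d(np.asarray(activity, float))
    n, T = A.shape
    if T < 2 * period_steps:
        raise ValueError("need at least two full periods")
    out = np.empty((n, period_steps))
    phases = np.arange(T) % period_steps
    for ph in range(period_steps):
        out[:, ph] = A[:, phases == ph].mean(axis=1)
    return out


def fourier_power(activity: np.ndarray, frequency: float,
                  fs: float = 1.0) -> np.ndarray:
    """Periodogram power at the DFT bin nearest ``frequency``.

    Normalised so the power summed over all bins equals sum(x^2)
    (Parseval).  Raises above the Nyquist frequency.
    """
    A = np.atleast_2d(np.asarray(activity, float))
    T = A.shape[1]
    if frequency > fs / 2:
        raise ValueError("frequency above Nyquist")
    F = np.fft.rfft(A, axis=1)
    power = np.abs(F) ** 2 / T
    # rfft folds negative frequencies: double interior bins
    if T % 2 == 0:
        power[:, 1:-1] *= 2
    else:
        power[:, 1:] *= 2
    freqs = np.fft.rfftfreq(T, d=1.0 / fs)
    bin_ = int(np.argmin(np.abs(freqs - frequency)))
    return power[:, bin_]
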