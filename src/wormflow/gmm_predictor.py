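"""Probabilistic per-neuron models: joint GMM over (U, y) and weights.

After gKDR reduces a target neuron's embedded presynaptic inputs x to
U = x B in R^K, the joint distribution of Z = (U(t), y(t+dt)) is fit
with a Gaussian mixture (kappa components; two in the whole-brain
models).  Prediction is the exact conditional mixture p(y | U): each
component contributes a Gaussian with

    w_q(U)  propto  pi_q N(U | mu_q^U, S_q^UU)
    m_q(U)  =  mu_q^y + S_q^yU (S_q^UU)^{-1} (U - mu_q^U)
    v_q     =  S_q^yy - S_q^yU (S_q^UU)^{-1} S_q^Uy.

The deterministic predictor is E(y|U) = sum_q w_q m_q; its gradient
with respect to x (chain rule through B) defines the model-estimated
*synaptic weight* after averaging over training time points and over
lags with geometric weights 0.8^k (k = 0 at the most recent lag):
positive values are excitatory-like, negative inhibitory-like.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp
from sklearn.mixture import GaussianMixture

from .connectome import STIM, ConnectomeGraph, build_presynaptic_set
from .embedding import embed_series, thin
from .gkdr import GkdrConfig, GkdrProjection, fit_gkdr, project
from .preprocess import ActivityMatrix

__all__ = [
    "GmmJointModel", "ConditionalDistribution", "NeuronModel", "BrainModel",
    "ModelHyper", "fit_gmm_joint", "conditional", "sample_conditional",
    "conditional_expectation", "expectation_gradient", "synaptic_weight",
    "build_design_matrix", "fit_neuron_model", "fit_brain_model",
    "LAG_DECAY",
]

#: geometric decay factor for lag aggregation of gradients
LAG_DECAY = 0.8


@dataclass
class GmmJointModel:
    """Joint Gaussian mixture over Z = (U, y); y is the last coordinate."""

    weights: np.ndarray        # (kappa,)
    means: np.ndarray          # (kappa, K+1)
    covariances: np.ndarray    # (kappa, K+1, K+1)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, float)
        self.means = np.asarray(self.means, float)
        self.covariances = np.asarray(self.covariances, float)
        if not np.isclose(self.weights.sum(), 1.0):
            raise ValueError("mixture weights must sum to 1")
        for S in self.covariances:
            if np.linalg.eigvalsh(S).min() <= 0:
                raise ValueError("covariances must be positive definite")

    @property
    def kappa(self) -> int:
        return self.weights.size

    @property
    def K(self) -> int:
        return self.means.shape[1] - 1


@dataclass
class ConditionalDistribution:
    """Mixture of 1-D Gaussians for y given a single U."""

    weights: np.ndarray
    means: np.ndarray
    variances: np.ndarray

    def pdf(self, y) -> np.ndarray:
        y = np.asarray(y, float)[..., None]
        comp = np.exp(-0.5 * (y - self.means) ** 2 / self.variances) \
            / np.sqrt(2 * np.pi * self.variances)
        return comp @ self.weights

    def mean(self) -> float:
        return float(self.weights @ self.means)

    def logpdf(self, y) -> np.ndarray:
        y = np.asarray(y, float)[..., None]
        lg = -0.5 * (y - self.means) ** 2 / self.variances \
            - 0.5 * np.log(2 * np.pi * self.variances) \
            + np.log(self.weights)
        return logsumexp(lg, axis=-1)


def fit_gmm_joint(Z: np.ndarray, kappa: int = 2, seed: int = 0, *,
                  n_init: int = 5, reg_covar: float = 1e-6,
                  max_restarts: int = 3) -> GmmJointModel:
    """EM fit of the joint mixture with seeded k-means initialisations.

    The best of ``n_init`` initialisations is kept; a degenerate fit
    (non-PD component after the covariance floor) is retried with a
    shifted seed up to ``max_restarts`` times.
    """
    Z = np.atleast_2d(np.asarray(Z, float))
    if kappa < 1:
        raise ValueError("kappa must be >= 1")
    if Z.shape[0] < 10 * Z.shape[1]:
        raise ValueError("need at least 10*(K+1) samples to fit the GMM")
    last_exc: Exception | None = None
    for attempt in range(max_restarts):
        gm = GaussianMixture(n_components=kappa, covariance_type="full",
                             n_init=n_init, reg_covar=reg_covar,
                             random_state=seed + attempt, max_iter=500)
        gm.fit(Z)
        try:
            return GmmJointModel(gm.weights_, gm.means_, gm.covariances_)
        except ValueError as exc:      # degenerate component
            last_exc = exc
    raise RuntimeError(f"GMM fit degenerate after {max_restarts} restarts"
                       ) from last_exc


def _component_conditionals(gmm: GmmJointModel):
    """Precompute per-component conditional pieces (U-independent)."""
    K = gmm.K
    pieces = []
    for q in range(gmm.kappa):
        S = gmm.covariances[q]
        Suu = S[:K, :K]
        Suy = S[:K, K]
        Syy = S[K, K]
        Suu_inv = np.linalg.inv(Suu)
        gain = Suu_inv @ Suy                       # R^K
        v = float(Syy - Suy @ gain)
        if v <= 0:
            raise ValueError("non-PD conditional variance")
        sign, logdet = np.linalg.slogdet(Suu)
        if sign <= 0:
            raise ValueError("non-PD U-marginal covariance")
        pieces.append((gmm.means[q, :K], float(gmm.means[q, K]),
                       Suu_inv, gain, v, logdet))
    return pieces


def _responsibilities(gmm: GmmJointModel, U: np.ndarray, pieces):
    """log w_q(U) for rows of U: posterior over components given U."""
    K = gmm.K
    U = np.atleast_2d(U)
    logw = np.empty((U.shape[0], gmm.kappa))
    for q, (muU, _, Suu_inv, _, _, logdet) in enumerate(pieces):
        d = U - muU
        maha = np.einsum("ij,jk,ik->i", d, Suu_inv, d)
        logw[:, q] = np.log(gmm.weights[q]) - 0.5 * (
            maha + logdet + K * np.log(2 * np.pi))
    return logw - logsumexp(logw, axis=1, keepdims=True)


def conditional(gmm: GmmJointModel, U) -> ConditionalDistribution:
    """Exact conditional mixture p(y | U) for one input point."""
    U = np.asarray(U, float).reshape(1, -1)
    if U.shape[1] != gmm.K:
        raise ValueError("U dimension mismatch")
    pieces = _component_conditionals(gmm)
    w = np.exp(_responsibilities(gmm, U, pieces)[0])
    means = np.array([muy + gain @ (U[0] - muU)
                      for (muU, muy, _, gain, _, _) in pieces])
    variances = np.array([v for (_, _, _, _, v, _) in pieces])
    return ConditionalDistribution(w, means, variances)


def conditional_batch(gmm: GmmJointModel, U: np.ndarray):
    """Vectorised conditional pieces for many rows of U.

    Returns (weights, means, variances) with shapes (n, kappa),
    (n, kappa), (kappa,).
    """
    U = np.atleast_2d(np.asarray(U, float))
    pieces = _component_conditionals(gmm)
    w = np.exp(_responsibilities(gmm, U, pieces))
    means = np.column_stack([muy + (U - muU) @ gain
                             for (muU, muy, _, gain, _, _) in pieces])
    variances = np.array([v for (_, _, _, _, v, _) in pieces])
    return w, means, variances


def sample_conditional(cond: ConditionalDistribution,
                       rng: np.random.Generator) -> float:
    """Draw a component by w_q, then a Gaussian draw from it."""
    q = rng.choice(cond.weights.size, p=cond.weights)
    return float(cond.means[q] + np.sqrt(cond.variances[q])
                 * rng.standard_normal())


def conditional_expectation(gmm: GmmJointModel, U) -> float:
    """Deterministic predictor E(y | U)."""
    return conditional(gmm, U).mean()


def expectation_gradient_U(gmm: GmmJointModel, U,
                           include_weight_gradient: bool = True
                           ) -> np.ndarray:
    """d E(y|U) / dU at a single point, analytic.

    The full gradient includes the U-dependence of the posterior
    component weights; ``include_weight_gradient=False`` keeps only the
    component-mean slopes (the simplified variant).
    """
    U = np.asarray(U, float).reshape(-1)
    pieces = _component_conditionals(gmm)
    w = np.exp(_responsibilities(gmm, U[None, :], pieces)[0])
    grads = np.array([gain for (_, _, _, gain, _, _) in pieces])
    means = np.array([muy + gain @ (U - muU)
                      for (muU, muy, _, gain, _, _) in pieces])
    g = w @ grads
    if include_weight_gradient and gmm.kappa > 1:
        # d log N_q / dU = -Suu_inv (U - muU); dw_q = w_q (dlogN_q - sum_r w_r dlogN_r)
        dlog = np.array([-Suu_inv @ (U - muU)
                         for (muU, _, Suu_inv, _, _, _) in pieces])
        avg = w @ dlog
        dw = w[:, None] * (dlog - avg)
        g = g + means @ dw
    return g


def expectation_gradient(model: "NeuronModel", x: np.ndarray,
                         include_weight_gradient: bool = True) -> np.ndarray:
    """d E(y)/dx over the embedded (neuron, lag) input coordinates."""
    x = np.asarray(x, float).reshape(-1)
    U = x @ model.projection.B
    gU = expectation_gradient_U(model.gmm, U, include_weight_gradient)
    return model.projection.B @ gU


def synaptic_weight(model: "NeuronModel", training_X: np.ndarray, *,
                    include_weight_gradient: bool = True,
                    decay: float = LAG_DECAY) -> dict[str, float]:
    """Lag-aggregated average gradient per presynaptic neuron.

    Gradients of the deterministic predictor are averaged over all
    training rows, then each neuron's lag profile is averaged with
    weights decay^k (k = 0 at the most recent lag), normalised by the
    geometric sum.  Positive => excitatory-like.
    """
    X = np.atleast_2d(np.asarray(training_X, float))
    B = model.projection.B
    U = X @ B
    gmm = model.gmm
    pieces = _component_conditionals(gmm)
    w, means, _ = conditional_batch(gmm, U)
    grads = np.array([gain for (_, _, _, gain, _, _) in pieces])
    gU = w @ grads                                  # (n, K)
    if include_weight_gradient and gmm.kappa > 1:
        dlog = np.stack([-(U - muU) @ Suu_inv
                         for (muU, _, Suu_inv, _, _, _) in pieces], axis=1)
        avg = np.einsum("nq,nqk->nk", w, dlog)
        dw = w[..., None] * (dlog - avg[:, None, :])
        gU = gU + np.einsum("nq,nqk->nk", means, dw)
    gx = gU.mean(axis=0) @ B.T                      # mean over time first
    kprime = model.kprime
    lag_w = decay ** np.arange(kprime)[::-1]        # oldest-first rows
    norm = lag_w.sum()
    out: dict[str, float] = {}
    for pos, neuron in enumerate(model.pset.explanatory):
        block = gx[pos * kprime: (pos + 1) * kprime]
        out[neuron] = float(block @ lag_w / norm)
    return out


@dataclass
class ModelHyper:
    """Hyperparameters of one gKDR-GMM fit."""

    K: int = 3
    kappa: int = 2
    kprime: int = 30
    tauprime: int = 10
    stride: int = 5
    offset: int = 0
    dt: int = 1                 # prediction horizon in thinned steps
    link_mode: str = "indirect"
    use_stimulus: bool = True
    gkdr_epsilon: float | None = None
    gkdr_max_points: int = 1000


@dataclass
class NeuronModel:
    """gKDR projection + joint GMM for one target neuron."""

    target: str
    pset: object                    # PresynapticSet
    projection: GkdrProjection
    gmm: GmmJointModel
    kprime: int
    tauprime: int
    stride: int
    offset: int
    dt: int
    residual_sd: float = 1.0        # sd of deterministic residuals (training)

    @property
    def input_dim(self) -> int:
        return len(self.pset.explanatory) * self.kprime


@dataclass
class BrainModel:
    """One animal's collection of per-neuron models plus wiring."""

    sample_id: str
    neuron_models: dict[str, NeuronModel]
    hyper: ModelHyper
    neuron_names: list[str]
    seed: int = 0

    @property
    def targets(self) -> list[str]:
        return list(self.neuron_models)


def build_design_matrix(sample: ActivityMatrix, pset, hyper: ModelHyper,
                        stimulus: np.ndarray | None = None):
    """Training matrices (X rows = thinned time points, y = target ahead).

    Each explanatory neuron contributes k' embedded coordinates
    (oldest lag first); columns are thinned to every ``stride``-th raw
    time point at the given offset, and the response is the target's
    activity ``dt`` thinned steps (dt*stride raw points) ahead.
    """
    k, tau, stride, offset = (hyper.kprime, hyper.tauprime, hyper.stride,
                              hyper.offset)
    horizon = hyper.dt * stride
    T = sample.n_time
    span = (k - 1) * tau
    blocks = []
    times = None
    for neuron in pset.explanatory:
        if neuron == STIM:
            if stimulus is None:
                raise ValueError("stimulus series required for STIM input")
            series = np.asarray(stimulus, float)[:T]
        else:
            series = sample.series(neuron)
        emb = embed_series(series, k, tau, neuron=neuron,
                           sample_id=sample.sample_id)
        emb = thin(emb, stride, offset)
        raw_t = np.array([t for (_, t) in emb.col_index])
        keep = raw_t + horizon <= T - 1
        blocks.append(emb.values[:, keep])
        times = raw_t[keep]
    X = np.vstack(blocks).T
    y = sample.series(pset.target)[times + horizon]
    col_index = [(neuron, lag) for neuron in pset.explanatory
                 for lag in range(k)]
    return X, y, times, col_index


def fit_neuron_model(sample: ActivityMatrix, graph: ConnectomeGraph,
                     target: str, hyper: ModelHyper, seed: int = 0,
                     stimulus: np.ndarray | None = None,
                     observed: set[str] | None = None) -> NeuronModel:
    """Fit gKDR then the joint GMM for one target neuron."""
    if observed is None:
        observed = set(sample.usable_neurons())
    pset = build_presynaptic_set(graph, target, observed, hyper.link_mode,
                                 hyper.use_stimulus and stimulus is not None)
    X, y, _, col_index = build_design_matrix(sample, pset, hyper, stimulus)
    if X.shape[0] == 0:
        raise ValueError(f"no training points for target {target}")
    cfg = GkdrConfig(K=min(hyper.K, X.shape[1]),
                     epsilon=hyper.gkdr_epsilon,
                     max_points=hyper.gkdr_max_points)
    proj = fit_gkdr(X, y, cfg, column_index=col_index)
    U = project(X, proj)
    Z = np.column_stack([U, y])
    gmm = fit_gmm_joint(Z, hyper.kappa, seed)
    w, means, _ = conditional_batch(gmm, U)
    pred = (w * means).sum(axis=1)
    residual_sd = float(np.std(y - pred))
    return NeuronModel(target, pset, proj, gmm, hyper.kprime,
                       hyper.tauprime, hyper.stride, hyper.offset, hyper.dt,
                       residual_sd)


def fit_brain_model(sample: ActivityMatrix, graph: ConnectomeGraph,
                    stimulus: np.ndarray | None, hyper: ModelHyper,
                    seed: int = 0) -> BrainModel:
    """One NeuronModel per usable (included & nonrandom) neuron."""
    import warnings as _warnings
    observed = set(sample.usable_neurons())
    models: dict[str, NeuronModel] = {}
    for i, target in enumerate(sorted(observed)):
        try:
            models[target] = fit_neuron_model(
                sample, graph, target, hyper, seed + i, stimulus, observed)
        except ValueError as exc:
            _warnings.warn(f"target {target} skipped: {exc}")
    return BrainModel(sample.sample_id, models, hyper,
                      list(sample.neuron_names), seed)
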