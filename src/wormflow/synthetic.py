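"""Ground-truth generators for end-to-end testing of the pipeline.

Three generators cover the statistical structures the methods assume:

* :func:`generate_motif_dataset` — multi-animal data composed of a few
  shared spatiotemporal motifs with sparse super-Gaussian occurrences.
  The factorization X_emb^T = W0 M0 + noise is planted directly in
  embedded (neuron x lag, time) space: an *exactly* low-rank
  delay-embedded (Hankel) matrix would force every trace to be a sum of
  a handful of exponential modes, which contradicts the sparse
  occurrence structure the motif model assumes, so the ground truth
  lives at the embedded level and raw traces are read off the newest
  lag row.  Recovery tests therefore consume the returned embedded
  matrices.

* :func:`generate_network_dataset` — nonlinear stochastic dynamics
  x(t+1) = tanh(A_chem x + A_gap x + b s(t)) + noise on a known sparse
  directed/undirected graph driven by a square-wave stimulus.  The
  emitted edge list hides the interaction signs, as a real anatomical
  connectome does, so sign inference can be scored against the ground
  truth.

* :func:`inject_missingness` — whole-neuron dropout per animal,
  mirroring how real recordings miss neurons per animal rather than
  scattered time points.

All generators are bitwise reproducible given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .embedding import EmbeddedMatrix
from .preprocess import ActivityMatrix
from .simulator import StimulusProtocol, make_salt_stimulus

__all__ = [
    "MotifGroundTruth", "NetworkGroundTruth",
    "generate_motif_dataset", "generate_network_dataset",
    "inject_missingness",
]


@dataclass
class MotifGroundTruth:
    M0: np.ndarray                    # n_motifs x (n_neurons*k)
    W0: dict[str, np.ndarray]         # sample -> (T_emb x n_motifs)
    noise_sd: float
    k: int
    seed: int


@dataclass
class NetworkGroundTruth:
    A_chem: np.ndarray                # signed directed weights
    A_gap: np.ndarray                 # symmetric nonnegative weights
    stimulus_gain: np.ndarray         # per-neuron stimulus coupling
    sensory: list[str]
    noise_sd: float
    stimulus: np.ndarray | None
    seed: int


def _smooth(x: np.ndarray, width: int) -> np.ndarray:
    """Moving-average smoothing along the last axis (reflect padding)."""
    if width <= 1:
        return x
    kernel = np.ones(width) / width
    pad = width // 2
    xp = np.concatenate([x[..., pad:0:-1], x, x[..., -2:-2 - pad:-1]],
                        axis=-1)
    out = np.apply_along_axis(lambda r: np.convolve(r, kernel, "same"),
                              -1, xp)
    return out[..., pad: pad + x.shape[-1]]


def generate_motif_dataset(n_neurons: int = 12, n_samples: int = 3,
                           T: int = 1500, n_motifs: int = 3,
                           sparsity: float = 0.9, noise_sd: float = 0.1,
                           seed: int = 0, k: int = 30):
    """Plant shared motifs with sample-specific sparse occurrences.

    Motifs are smooth random (neuron x lag) patterns, identical across
    animals; occurrences are sparse Laplace series (fraction ``sparsity``
    of time points zeroed, then smoothed) that differ per animal.  Each
    animal's embedded matrix is X_emb = (W0 M0)^T + Gaussian noise.

    Returns ``(activities, embedded, truth)``: raw-trace
    :class:`ActivityMatrix` per animal (newest-lag readout), the planted
    embedded matrices, and the ground truth.
    """
    if n_motifs > n_neurons:
        raise ValueError("n_motifs cannot exceed n_neurons")
    if not 0 <= sparsity < 1:
        raise ValueError("sparsity must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    T_emb = T - (k - 1)
    if T_emb < 10:
        raise ValueError("T too short for the embedding window")
    names = [f"N{i:02d}" for i in range(n_neurons)]
    # smooth motif patterns over the delay axis, random spatial loadings
    M0 = np.empty((n_motifs, n_neurons * k))
    for c in range(n_motifs):
        pattern = _smooth(rng.standard_normal((n_neurons, k)), k // 4)
        pattern /= np.abs(pattern).max()
        M0[c] = pattern.ravel()
    activities, embedded = [], []
    W0: dict[str, np.ndarray] = {}
    for j in range(n_samples):
        sid = f"sample{j}"
        W = rng.laplace(size=(T_emb, n_motifs))
        mask = rng.random((T_emb, n_motifs)) < sparsity
        W[mask] = 0.0
        W = _smooth(W.T, 5).T
        W0[sid] = W
        X_emb = (W @ M0).T + noise_sd * rng.standard_normal(
            (n_neurons * k, T_emb))
        row_index = [(nm, lag) for nm in names for lag in range(k)]
        col_index = [(sid, t) for t in range(k - 1, T)]
        emb = EmbeddedMatrix(X_emb, row_index, col_index, k, 1)
        # raw readout: oldest lags of the first column, then newest row
        values = np.empty((n_neurons, T))
        for i in range(n_neurons):
            rows = emb.rows_for(names[i])
            values[i, : k - 1] = X_emb[rows[:-1], 0]
            values[i, k - 1:] = X_emb[rows[-1]]
        activities.append(ActivityMatrix(
            sid, list(names), values,
            np.ones(n_neurons, bool), np.ones(n_neurons, bool)))
        embedded.append(emb)
    return activities, embedded, MotifGroundTruth(M0, W0, noise_sd, k, seed)


def generate_network_dataset(n_neurons: int = 12, edge_density: float = 0.25,
                             frac_gap: float = 0.2,
                             frac_inhibitory: float = 0.35,
                             noise_sd: float = 0.1,
                             stimulus: StimulusProtocol | None = None,
                             T: int = 1500, seed: int = 0, *,
                             coupling: float = 1.0,
                             n_sensory: int = 2,
                             sample_id: str = "net0"):
    """Simulate tanh network dynamics on a known sparse graph.

    x(t+1) = tanh(A x(t) + b s(t)) + eps(t), A = A_chem + A_gap; A_chem
    is sparse, directed and signed (fraction ``frac_inhibitory``
    negative), A_gap symmetric nonnegative; the square-wave stimulus
    (standardised) feeds the first ``n_sensory`` neurons.  A is rescaled
    with a warning if its spectral radius reaches 1.

    Returns ``(activity, edge_list, truth)``: an :class:`ActivityMatrix`,
    an unsigned edge-list DataFrame (columns pre, post, type, count) and
    the signed ground truth.
    """
    import warnings
    rng = np.random.default_rng(seed)
    names = [f"N{i:02d}" for i in range(n_neurons)]
    n_edges = max(1, int(round(edge_density * n_neurons * (n_neurons - 1))))
    n_gap = int(round(frac_gap * n_edges))
    n_chem = n_edges - n_gap
    pairs = [(i, j) for i in range(n_neurons) for j in range(n_neurons)
             if i != j]
    chem_idx = rng.choice(len(pairs), size=n_chem, replace=False)
    A_chem = np.zeros((n_neurons, n_neurons))
    for e in chem_idx:
        i, j = pairs[e]
        w = rng.uniform(0.5, 1.5)
        if rng.random() < frac_inhibitory:
            w = -w
        A_chem[j, i] = w          # row = post, col = pre
    A_gap = np.zeros((n_neurons, n_neurons))
    upper = [(i, j) for i in range(n_neurons) for j in range(i + 1, n_neurons)]
    gap_idx = rng.choice(len(upper), size=min(n_gap, len(upper)),
                         replace=False)
    for e in gap_idx:
        i, j = upper[e]
        w = rng.uniform(0.25, 0.75)
        A_gap[i, j] = A_gap[j, i] = w
    A = A_chem + A_gap
    radius = np.max(np.abs(np.linalg.eigvals(A)))
    target_radius = 0.9 * coupling
    if target_radius >= 1.0:
        warnings.warn("requested coupling gives spectral radius >= 1; "
                      "rescaled to 0.95 for stability")
        target_radius = 0.95
    if radius > 0:
        scale = target_radius / radius
        A *= scale
        A_chem *= scale
        A_gap *= scale
    sensory = names[:n_sensory]
    gain = np.zeros(n_neurons)
    if stimulus is not None and stimulus.kind != "none":
        gain[:n_sensory] = rng.uniform(0.5, 1.0, n_sensory)
        s = make_salt_stimulus(stimulus, T)
        s = (s - s.mean()) / s.std() if s.std() > 0 else s * 0.0
    else:
        s = np.zeros(T)
    x = np.zeros(n_neurons)
    values = np.empty((n_neurons, T))
    for t in range(T):
        x = np.tanh(A @ x + gain * s[t]) \
            + noise_sd * rng.standard_normal(n_neurons)
        values[:, t] = x
    rows = []
    for i in range(n_neurons):
        for j in range(n_neurons):
            if A_chem[j, i] != 0:
                rows.append({"pre": names[i], "post": names[j],
                             "type": "chemical", "count": 1})
    for i, j in upper:
        if A_gap[i, j] != 0:
            rows.append({"pre": names[i], "post": names[j],
                         "type": "gap", "count": 1})
    edge_list = pd.DataFrame(rows, columns=["pre", "post", "type", "count"])
    activity = ActivityMatrix(sample_id, names, values,
                              np.ones(n_neurons, bool),
                              np.ones(n_neurons, bool))
    truth = NetworkGroundTruth(A_chem, A_gap, gain, sensory, noise_sd,
                               s if stimulus is not None else None, seed)
    return activity, edge_list, truth


def inject_missingness(activities, fractions, seed: int = 0):
    """Mask whole neurons per animal (activity rows set to NaN).

    ``fractions`` is one missing fraction per animal; the number of
    masked neurons is round(fraction * n).  A neuron masked in *every*
    animal would be uncompletable and is rejected.

    Returns ``(masked_activities, mask)`` where ``mask[sample][i]`` is
    True for a masked neuron.
    """
    activities = list(activities)
    fractions = list(fractions)
    if len(fractions) != len(activities):
        raise ValueError("one fraction per sample required")
    if any(not 0 <= f < 1 for f in fractions):
        raise ValueError("fractions must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    masks: dict[str, np.ndarray] = {}
    out = []
    n = activities[0].n_neurons
    last = len(activities) - 1
    everywhere = np.ones(n, dtype=bool)
    for s, (a, f) in enumerate(zip(activities, fractions)):
        n_mask = int(round(f * a.n_neurons))
        # redraw so no neuron ends up masked in every sample (it would
        # have zero observations and be uncompletable)
        mask = None
        for _ in range(200):
            idx = rng.choice(a.n_neurons, size=n_mask, replace=False)
            cand = np.zeros(a.n_neurons, dtype=bool)
            cand[idx] = True
            if s < last or not (everywhere & cand).any():
                mask = cand
                break
        if mask is None or (s == last and (everywhere & mask).any()):
            raise ValueError(
                "cannot avoid masking a neuron in all samples; lower the "
                "missing fractions")
        values = a.values.copy()
        values[mask] = np.nan
        masks[a.sample_id] = mask
        everywhere &= mask
        out.append(ActivityMatrix(a.sample_id, list(a.neuron_names), values,
                                  a.included_mask & ~mask,
                                  a.nonrandom_mask & ~mask, a.frame_rate))
    if everywhere.any():
        raise ValueError("a neuron is masked in all samples; uncompletable")
    return out, masks
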