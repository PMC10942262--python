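"""Shared fixtures: planted-motif datasets, fitted models, toy mixtures.

Expensive objects (RICA fits, whole-network model fits) are built once
per session and reused by both the unit and the acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from wormflow.connectome import ConnectomeGraph
from wormflow.embedding import EmbeddedMatrix  # noqa: F401 (fixture use)
from wormflow.gmm_predictor import (GmmJointModel, ModelHyper,
                                    fit_brain_model)
from wormflow.synthetic import generate_motif_dataset, generate_network_dataset
from wormflow.tde_rica import fit_rica


def stack_embedded(embs) -> EmbeddedMatrix:
    """Concatenate per-sample embedded matrices along the time axis."""
    values = np.hstack([e.values for e in embs])
    col_index = [c for e in embs for c in e.col_index]
    return EmbeddedMatrix(values, list(embs[0].row_index), col_index,
                          embs[0].k, embs[0].tau)


def graph_from_edges(df) -> ConnectomeGraph:
    g = ConnectomeGraph()
    for r in df.itertuples(index=False):
        g.add_edge(r.pre, r.post, r.type, r.count)
    return g


#: embedding/model hyperparameters matched to the synthetic network's
#: one-step dynamics (the real-data values k'=30, tau'=10, stride 5 span
#: the same construction at the recording's slower timescale)
NET_HYPER = ModelHyper(K=2, kappa=2, kprime=5, tauprime=1, stride=1,
                       offset=0, dt=1, link_mode="direct",
                       use_stimulus=False, gkdr_max_points=800)


@pytest.fixture(scope="session")
def motif_bundle():
    """Planted-motif data (noise sd 0.1) with a fitted RICA model."""
    activities, embs, truth = generate_motif_dataset(
        n_neurons=12, n_samples=3, T=1500, n_motifs=3, noise_sd=0.1, seed=0)
    X = stack_embedded(embs)
    model = fit_rica(X, 3, 1.0, seed=0)
    return {"activities": activities, "embedded": embs, "X": X,
            "truth": truth, "model": model}


@pytest.fixture(scope="session")
def completion_bundle():
    """Low-noise planted data with two neurons masked in one sample each;
    model fitted on the 10-neuron, 2-sample complete block, then extended
    by masked matrix factorization.  ``rel_rmse`` holds the relative
    error of the completed entries against the noiseless ground truth."""
    from wormflow.tde_rica import complete_by_matrix_factorization

    acts, embs, truth = generate_motif_dataset(
        12, 3, 1500, 3, noise_sd=0.01, seed=1)
    names = acts[0].neuron_names
    old = names[:10]
    sub = []
    for e in embs[:2]:
        rows = np.concatenate([e.rows_for(n) for n in old])
        sub.append(EmbeddedMatrix(e.values[rows],
                                  [e.row_index[r] for r in rows],
                                  list(e.col_index), e.k, e.tau))
    model = fit_rica(stack_embedded(sub), 3, 1.0, seed=0)
    X_all = stack_embedded(embs)
    X_all = EmbeddedMatrix(X_all.values.copy(), X_all.row_index,
                           X_all.col_index, X_all.k, X_all.tau)
    masked = [("N10", "sample0"), ("N11", "sample1")]
    for neuron, sid in masked:
        X_all.values[np.ix_(X_all.rows_for(neuron),
                            X_all.columns_for(sid))] = np.nan
    ext = complete_by_matrix_factorization(X_all, model, seed=0)

    k = truth.k
    recon = (ext.W_all @ ext.M_all).T
    col_off, off = {}, 0
    for sid in ext.sample_order:
        col_off[sid] = off
        off += truth.W0[sid].shape[0]
    err, ref = [], []
    for neuron, sid in masked:
        fi = ext.neuron_order.index(neuron)
        rows = np.arange(fi * k, (fi + 1) * k)
        cols = np.arange(col_off[sid], col_off[sid] + truth.W0[sid].shape[0])
        pred = recon[np.ix_(rows, cols)]
        ti = names.index(neuron)
        true = (truth.W0[sid] @ truth.M0).T[ti * k: (ti + 1) * k]
        err.append((pred - true).ravel())
        ref.append(true.ravel())
    err, ref = np.concatenate(err), np.concatenate(ref)
    rel_rmse = float(np.sqrt(np.mean(err ** 2)) / np.sqrt(np.mean(ref ** 2)))
    return {"truth": truth, "ext": ext, "masked": masked, "names": names,
            "model": model, "X_all": X_all, "rel_rmse": rel_rmse}


@pytest.fixture(scope="session")
def network_bundle():
    """Simulated tanh network with a fitted whole-brain model."""
    activity, edges, truth = generate_network_dataset(
        n_neurons=12, T=1500, noise_sd=0.15, stimulus=None, seed=0)
    graph = graph_from_edges(edges)
    brain = fit_brain_model(activity, graph, None, NET_HYPER, seed=0)
    return {"activity": activity, "edges": edges, "graph": graph,
            "truth": truth, "brain": brain, "hyper": NET_HYPER}


@pytest.fixture(scope="session")
def toy_gmm2():
    """Well-separated 2-component joint mixture over (U, y), K=2."""
    means = np.array([[0.0, 0.0, 1.0],
                      [2.0, -1.0, -1.0]])
    cov0 = np.array([[1.0, 0.3, 0.4],
                     [0.3, 1.5, -0.2],
                     [0.4, -0.2, 0.8]])
    cov1 = np.array([[0.7, -0.2, 0.1],
                     [-0.2, 1.2, 0.5],
                     [0.1, 0.5, 1.5]])
    return GmmJointModel(np.array([0.6, 0.4]), means,
                         np.stack([cov0, cov1]))
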