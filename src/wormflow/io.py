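"""Readers and writers for the pipeline's on-disk formats.

Delimited text: rows = neurons, first column = neuron name, header row =
time indices, empty cell = missing.  The HDF5 container mirrors the same
layout and also serializes embedded matrices, fitted brain models and
simulation traces so runs are exactly reproducible.
"""

from __future__ import annotations

import json

import h5py
import numpy as np
import pandas as pd

from .connectome import PresynapticSet
from .embedding import EmbeddedMatrix
from .gkdr import GkdrProjection
from .gmm_predictor import (BrainModel, GmmJointModel, ModelHyper,
                            NeuronModel)
from .preprocess import ActivityMatrix, RawFluorescenceTable
from .simulator import SimulationTrace

__all__ = [
    "write_activity_csv", "read_activity_csv",
    "write_fluorescence_csv", "read_fluorescence_csv",
    "save_activity_h5", "load_activity_h5",
    "save_embedded_h5", "load_embedded_h5",
    "save_brain_model", "load_brain_model",
    "save_trace", "load_trace",
]

_STR = h5py.string_dtype(encoding="utf-8")


def _frame(names, values) -> pd.DataFrame:
    df = pd.DataFrame(values, index=pd.Index(names, name="neuron"),
                      columns=np.arange(values.shape[1]))
    return df


def write_activity_csv(activity: ActivityMatrix, path, sep=",") -> None:
    _frame(activity.neuron_names, activity.values).to_csv(path, sep=sep)


def read_activity_csv(path, sample_id: str | None = None,
                      sep=None) -> ActivityMatrix:
    df = pd.read_csv(path, index_col=0, sep=sep, engine="python")
    values = df.to_numpy(dtype=float)
    included = np.isfinite(values).all(axis=1)
    nonrandom = included.copy()
    sid = sample_id if sample_id is not None else str(path)
    return ActivityMatrix(sid, [str(n) for n in df.index], values,
                          included, nonrandom)


def write_fluorescence_csv(raw: RawFluorescenceTable, cfp_path,
                           yfp_path, sep=",") -> None:
    _frame(raw.neuron_names, raw.cfp).to_csv(cfp_path, sep=sep)
    _frame(raw.neuron_names, raw.yfp).to_csv(yfp_path, sep=sep)


def read_fluorescence_csv(cfp_path, yfp_path, sample_id: str,
                          frame_rate: float = 4.0,
                          sep=None) -> RawFluorescenceTable:
    cfp = pd.read_csv(cfp_path, index_col=0, sep=sep, engine="python")
    yfp = pd.read_csv(yfp_path, index_col=0, sep=sep, engine="python")
    if list(cfp.index) != list(yfp.index):
        raise ValueError("CFP and YFP tables list different neurons")
    return RawFluorescenceTable(sample_id, [str(n) for n in cfp.index],
                                cfp.to_numpy(float), yfp.to_numpy(float),
                                frame_rate)


def save_activity_h5(activity: ActivityMatrix, path) -> None:
    with h5py.File(path, "w") as f:
        g = f.create_group("activity")
        g.create_dataset("values", data=activity.values)
        g.create_dataset("neuron_names",
                         data=np.array(activity.neuron_names, dtype=_STR))
        g.create_dataset("included_mask", data=activity.included_mask)
        g.create_dataset("nonrandom_mask", data=activity.nonrandom_mask)
        g.attrs["sample_id"] = activity.sample_id
        g.attrs["frame_rate"] = activity.frame_rate


def load_activity_h5(path) -> ActivityMatrix:
    with h5py.File(path, "r") as f:
        g = f["activity"]
        return ActivityMatrix(
            g.attrs["sample_id"],
            [n.decode() if isinstance(n, bytes) else str(n)
             for n in g["neuron_names"][()]],
            g["values"][()], g["included_mask"][()],
            g["nonrandom_mask"][()], float(g.attrs["frame_rate"]))


def save_embedded_h5(emb: EmbeddedMatrix, path) -> None:
    with h5py.File(path, "w") as f:
        g = f.create_group("embedded")
        g.create_dataset("values", data=emb.values)
        g.create_dataset("row_neuron",
                         data=np.array([r[0] for r in emb.row_index],
                                       dtype=_STR))
        g.create_dataset("row_lag",
                         data=np.array([r[1] for r in emb.row_index]))
        g.create_dataset("col_sample",
                         data=np.array([c[0] for c in emb.col_index],
                                       dtype=_STR))
        g.create_dataset("col_time",
                         data=np.array([c[1] for c in emb.col_index]))
        g.attrs["k"] = emb.k
        g.attrs["tau"] = emb.tau


def load_embedded_h5(path) -> EmbeddedMatrix:
    def dec(x):
        return x.decode() if isinstance(x, bytes) else str(x)
    with h5py.File(path, "r") as f:
        g = f["embedded"]
        row_index = [(dec(n), int(l)) for n, l in
                     zip(g["row_neuron"][()], g["row_lag"][()])]
        col_index = [(dec(s), int(t)) for s, t in
                     zip(g["col_sample"][()], g["col_time"][()])]
        return EmbeddedMatrix(g["values"][()], row_index, col_index,
                              int(g.attrs["k"]), int(g.attrs["tau"]))


def save_brain_model(brain: BrainModel, path) -> None:
    hyper = brain.hyper.__dict__.copy()
    with h5py.File(path, "w") as f:
        f.attrs["sample_id"] = brain.sample_id
        f.attrs["seed"] = brain.seed
        f.attrs["hyper"] = json.dumps(hyper)
        f.create_dataset("neuron_names",
                         data=np.array(brain.neuron_names, dtype=_STR))
        for name, m in brain.neuron_models.items():
            g = f.create_group(f"models/{name}")
            g.attrs["target"] = m.target
            g.attrs["link_mode"] = m.pset.link_mode
            g.attrs["residual_sd"] = m.residual_sd
            g.attrs["params"] = json.dumps(
                {"kprime": m.kprime, "tauprime": m.tauprime,
                 "stride": m.stride, "offset": m.offset, "dt": m.dt})
            g.create_dataset("explanatory",
                             data=np.array(m.pset.explanatory, dtype=_STR))
            g.create_dataset("B", data=m.projection.B)
            g.create_dataset("eigenvalues", data=m.projection.eigenvalues)
            g.attrs["sigma_x"] = m.projection.sigma_x
            g.attrs["sigma_y"] = m.projection.sigma_y
            g.attrs["epsilon"] = m.projection.epsilon
            g.create_dataset("gmm_weights", data=m.gmm.weights)
            g.create_dataset("gmm_means", data=m.gmm.means)
            g.create_dataset("gmm_covariances", data=m.gmm.covariances)


def load_brain_model(path) -> BrainModel:
    def dec(x):
        return x.decode() if isinstance(x, bytes) else str(x)
    with h5py.File(path, "r") as f:
        hyper = ModelHyper(**json.loads(f.attrs["hyper"]))
        models: dict[str, NeuronModel] = {}
        if "models" in f:
            for name in f["models"]:
                g = f[f"models/{name}"]
                p = json.loads(g.attrs["params"])
                pset = PresynapticSet(
                    g.attrs["target"],
                    [dec(n) for n in g["explanatory"][()]],
                    g.attrs["link_mode"])
                proj = GkdrProjection(g["B"][()], g["eigenvalues"][()],
                                      float(g.attrs["sigma_x"]),
                                      float(g.attrs["sigma_y"]),
                                      float(g.attrs["epsilon"]))
                gmm = GmmJointModel(g["gmm_weights"][()],
                                    g["gmm_means"][()],
                                    g["gmm_covariances"][()])
                models[name] = NeuronModel(
                    g.attrs["target"], pset, proj, gmm, p["kprime"],
                    p["tauprime"], p["stride"], p["offset"], p["dt"],
                    float(g.attrs["residual_sd"]))
        return BrainModel(f.attrs["sample_id"], models, hyper,
                          [dec(n) for n in f["neuron_names"][()]],
                          int(f.attrs["seed"]))


def save_trace(trace: SimulationTrace, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=trace.values)
        f.create_dataset("neuron_names",
                         data=np.array(trace.neuron_names, dtype=_STR))
        f.attrs["mode"] = trace.mode
        f.attrs["seed"] = trace.seed
        f.attrs["n_init"] = trace.n_init
        if trace.stimulus is not None:
            f.create_dataset("stimulus", data=trace.stimulus)


def load_trace(path) -> SimulationTrace:
    def dec(x):
        return x.decode() if isinstance(x, bytes) else str(x)
    with h5py.File(path, "r") as f:
        stim = f["stimulus"][()] if "stimulus" in f else None
        return SimulationTrace(f["values"][()],
                               [dec(n) for n in f["neuron_names"][()]],
                               f.attrs["mode"], int(f.attrs["seed"]),
                               int(f.attrs["n_init"]), stim)
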