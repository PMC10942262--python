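"""Time-delay embedding shared by the motif and regression pipelines.

A series x(t) of length T is expanded into columns
[x(t-(k-1)τ), ..., x(t-τ), x(t)] for t = (k-1)τ .. T-1, giving
T - (k-1)τ valid columns.  Lags are ordered oldest-first within each
neuron's row block; ``row_index`` and ``col_index`` make the layout
explicit so consumers never rely on ordering conventions.

Two parameterisations are used downstream: k=300, τ=1 for motif
extraction (TDE-RICA) and k'=30, τ'=10 for the per-neuron regression
models, where additionally only every 5th embedded column (an offset
phase of the thinning) is kept to make the kernel computations feasible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["EmbeddedMatrix", "embed_series", "embed_stack", "thin"]


@dataclass
class EmbeddedMatrix:
    """Delay-embedded design matrix with explicit index maps.

    values : (n_neurons*k) x n_columns array, possibly NaN where the
        underlying neuron is unobserved.
    row_index : list of (neuron, lag) per row, lag 0..k-1 oldest-first.
    col_index : list of (sample_id, time) per column; ``time`` is the
        0-based raw index of the newest entry of the column.
    """

    values: np.ndarray
    row_index: list[tuple[str, int]]
    col_index: list[tuple[str, int]]
    k: int
    tau: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.row_index), len(self.col_index)):
            raise ValueError("index maps inconsistent with values shape")

    @property
    def n_columns(self) -> int:
        return self.values.shape[1]

    @property
    def neurons(self) -> list[str]:
        seen: dict[str, None] = {}
        for name, lag in self.row_index:
            if lag == 0:
                seen[name] = None
        return list(seen)

    @property
    def samples(self) -> list[str]:
        seen: dict[str, None] = {}
        for sid, _ in self.col_index:
            seen[sid] = None
        return list(seen)

    def rows_for(self, neuron: str) -> np.ndarray:
        """Row indices of one neuron's lag block, oldest lag first."""
        idx = [r for r, (name, _) in enumerate(self.row_index) if name == neuron]
        if not idx:
            raise KeyError(neuron)
        return np.asarray(idx)

    def columns_for(self, sample_id: str) -> np.ndarray:
        return np.asarray([c for c, (sid, _) in enumerate(self.col_index)
                           if sid == sample_id])


def embed_series(x: np.ndarray, k: int, tau: int, *,
                 neuron: str = "x", sample_id: str = "0") -> EmbeddedMatrix:
    """Delay-embed one series; columns are the valid time points."""
    x = np.asarray(x, dtype=float)
    if k < 1 or tau < 1:
        raise ValueError("k and tau must be positive integers")
    T = x.size
    span = (k - 1) * tau
    if T < span + 1:
        raise ValueError(
            f"series too short for embedding: need at least {span + 1} "
            f"points (k={k}, tau={tau}), got {T}")
    n_cols = T - span
    # column t holds x at t-span, t-span+tau, ..., t  (oldest first)
    values = np.empty((k, n_cols))
    for lag in range(k):
        start = lag * tau
        values[lag] = x[start: start + n_cols]
    row_index = [(neuron, lag) for lag in range(k)]
    col_index = [(sample_id, t) for t in range(span, T)]
    return EmbeddedMatrix(values, row_index, col_index, k, tau)


def embed_stack(activities, k: int, tau: int,
                neurons: list[str] | None = None) -> EmbeddedMatrix:
    """Embed several samples and concatenate columns.

    All samples must provide complete traces for the common neuron set
    (pass ``neurons`` to select a subset); rows are stacked neuron-major,
    each neuron contributing k rows.
    """
    activities = list(activities)
    if not activities:
        raise ValueError("need at least one sample")
    if neurons is None:
        neurons = [n for n in activities[0].neuron_names
                   if all(n in a.neuron_names for a in activities)]
    for a in activities:
        missing = [n for n in neurons if n not in a.neuron_names]
        if missing:
            raise ValueError(f"sample {a.sample_id} lacks neurons {missing}")
    blocks = []
    col_index: list[tuple[str, int]] = []
    row_index: list[tuple[str, int]] = []
    first = True
    for a in activities:
        per_neuron = []
        for n in neurons:
            emb = embed_series(a.series(n), k, tau, neuron=n,
                               sample_id=a.sample_id)
            per_neuron.append(emb.values)
            if first:
                row_index.extend(emb.row_index)
        first = False
        blocks.append(np.vstack(per_neuron))
        span = (k - 1) * tau
        col_index.extend((a.sample_id, t) for t in range(span, a.n_time))
    values = np.hstack(blocks)
    return EmbeddedMatrix(values, row_index, col_index, k, tau)


def thin(x, stride: int = 5, offset: int = 0):
    """Keep every ``stride``-th time point, phase ``offset``.

    For a plain 1-D series the raw index is used; for an
    :class:`EmbeddedMatrix` the column's raw time (newest entry) is used,
    so the five offsets partition the embedded columns exactly.
    """
    if stride < 1:
        raise ValueError("stride must be positive")
    if not 0 <= offset < stride:
        raise ValueError("offset must lie in 0..stride-1")
    if isinstance(x, EmbeddedMatrix):
        keep = [c for c, (_, t) in enumerate(x.col_index)
                if t % stride == offset]
        return EmbeddedMatrix(x.values[:, keep], list(x.row_index),
                              [x.col_index[c] for c in keep], x.k, x.tau)
    arr = np.asarray(x)
    return arr[offset::stride]
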