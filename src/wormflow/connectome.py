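"""Connectome handling and presynaptic-set construction.

Chemical synapses are directed (pre -> post); gap junctions are
undirected and treated as bidirectional connections.  For each target
neuron the regression models use the delay-embedded activity of its
"presynaptic" neurons — its direct chemical inputs and gap partners,
always including the target's own history — restricted to neurons that
are actually observed (and non-random) in the given animal.  Because
roughly half of the head neurons are typically missing from a
recording, an *indirect* mode substitutes each unobserved direct input
with that neuron's own observed inputs (one extra synaptic step).
Salt-sensing neurons additionally receive the stimulus trace as a
pseudo-neuron ``STIM``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

__all__ = [
    "ConnectomeGraph",
    "PresynapticSet",
    "SALT_SENSORS",
    "STIM",
    "read_edge_list",
    "presynaptic_direct",
    "presynaptic_indirect",
    "augment_with_stimulus",
    "build_presynaptic_set",
]

#: pseudo-neuron label carrying the stimulus series
STIM = "STIM"

#: neurons that receive the salt stimulus as an extra presynaptic input
SALT_SENSORS = frozenset(
    ["ASEL", "ASER", "AWCL", "AWCR", "BAGL", "BAGR", "ASHL", "ASHR"])


@dataclass
class ConnectomeGraph:
    """Aggregated chemical (directed) + gap (undirected) connectivity."""

    chemical: nx.DiGraph = field(default_factory=nx.DiGraph)
    gap: nx.Graph = field(default_factory=nx.Graph)

    @property
    def nodes(self) -> set[str]:
        return set(self.chemical.nodes) | set(self.gap.nodes)

    def add_edge(self, pre: str, post: str, kind: str, count: float = 1):
        if kind == "chemical":
            if pre == post:
                warnings.warn(f"self-loop chemical edge kept: {pre}")
            w = self.chemical.get_edge_data(pre, post, {"count": 0})["count"]
            self.chemical.add_edge(pre, post, count=w + count)
        elif kind == "gap":
            w = self.gap.get_edge_data(pre, post, {"count": 0})["count"]
            self.gap.add_edge(pre, post, count=w + count)
        else:
            raise ValueError(f"unknown synapse type: {kind!r}")

    def inputs(self, target: str) -> set[str]:
        """Chemical presynaptic partners plus gap partners of target."""
        pre = set()
        if target in self.chemical:
            pre |= set(self.chemical.predecessors(target))
        if target in self.gap:
            pre |= set(self.gap.neighbors(target))
        return pre


@dataclass
class PresynapticSet:
    """Explanatory neurons for one target in one animal."""

    target: str
    explanatory: list[str]          # observed neurons, target included
    link_mode: str                  # "direct" | "indirect"
    provenance: dict[str, str] = field(default_factory=dict)
    # provenance maps a substituted neuron -> the missing intermediate

    def __post_init__(self) -> None:
        if self.target not in self.explanatory:
            raise ValueError("target must be part of its explanatory set")

    @property
    def size(self) -> int:
        return len(self.explanatory)


def read_edge_list(path) -> ConnectomeGraph:
    """Load a delimited edge list (columns: pre, post, type, count).

    Duplicate rows are aggregated by summing counts; chemical edges stay
    directed, gap edges become undirected.  Comma or tab delimited.
    """
    import csv as _csv
    try:
        df = pd.read_csv(path, sep=None, engine="python")
    except (pd.errors.EmptyDataError, _csv.Error):
        return ConnectomeGraph()
    required = {"pre", "post", "type"}
    if not required <= set(df.columns):
        raise ValueError(f"edge list needs columns {sorted(required)}")
    if "count" not in df.columns:
        df["count"] = 1
    g = ConnectomeGraph()
    for row in df.itertuples(index=False):
        g.add_edge(str(row.pre), str(row.post), str(row.type),
                   float(row.count))
    return g


def _ordered(pre: set[str], target: str) -> list[str]:
    """Deterministic explanatory order: sorted inputs, target last."""
    return sorted(pre - {target}) + [target]


def presynaptic_direct(graph: ConnectomeGraph, target: str,
                       observed: set[str]) -> PresynapticSet:
    """Observed direct inputs (chemical in-edges + gap partners) + self."""
    observed = set(observed)
    if target not in graph.nodes:
        warnings.warn(f"target {target} not in connectome; self-history only")
        return PresynapticSet(target, [target], "direct")
    pre = graph.inputs(target) & observed
    return PresynapticSet(target, _ordered(pre, target), "direct")


def presynaptic_indirect(graph: ConnectomeGraph, target: str,
                         observed: set[str]) -> PresynapticSet:
    """Direct set, with unobserved inputs replaced by their own inputs.

    Exactly one extra synaptic step: an unobserved input m contributes
    its observed inputs (chemical and gap); inputs of m that are also
    unobserved are dropped, never recursed into.
    """
    observed = set(observed)
    if target not in graph.nodes:
        warnings.warn(f"target {target} not in connectome; self-history only")
        return PresynapticSet(target, [target], "indirect")
    direct = graph.inputs(target)
    pre = direct & observed
    provenance: dict[str, str] = {}
    for m in sorted(direct - observed):
        for sub in graph.inputs(m) & observed:
            if sub not in pre:
                provenance[sub] = m
            pre.add(sub)
    return PresynapticSet(target, _ordered(pre, target), "indirect",
                          provenance)


def augment_with_stimulus(pset: PresynapticSet,
                          sensory_list=SALT_SENSORS) -> PresynapticSet:
    """Append the ``STIM`` pseudo-neuron for salt-sensor targets.

    Idempotent; non-sensor targets are returned unchanged.
    """
    if pset.target not in sensory_list or STIM in pset.explanatory:
        return pset
    return PresynapticSet(pset.target, pset.explanatory + [STIM],
                          pset.link_mode, dict(pset.provenance))


def build_presynaptic_set(graph: ConnectomeGraph, target: str,
                          observed: set[str], link_mode: str = "indirect",
                          use_stimulus: bool = True) -> PresynapticSet:
    if link_mode == "direct":
        pset = presynaptic_direct(graph, target, observed)
    elif link_mode == "indirect":
        pset = presynaptic_indirect(graph, target, observed)
    else:
        raise ValueError(f"unknown link mode {link_mode!r}")
    if use_stimulus:
        pset = augment_with_stimulus(pset)
    return pset
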