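"""Disease-subnetwork construction and k-core topology.

The disease subnetwork is the subgraph induced by the top-ranked genes,
keeping only interactions at or above a confidence floor (0.5 is the usual
medium-confidence cut for STRING-style scores).  Its topology is summarized
by k-core decomposition: the k-core is the maximal subgraph in which every
node keeps degree >= k, obtained by recursively peeling minimum-degree
nodes; the k-core layer l_k holds the nodes whose core number is exactly k.
A three-way core-periphery partition (inner / medium / outer) then follows
from two core-number cutpoints.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd
from scipy import sparse

from .prioritize import WeightedNetwork

__all__ = [
    "Subnetwork",
    "CoreDecomposition",
    "CorePeripheryPartition",
    "extract_subnetwork",
    "k_core_decompose",
    "core_layers",
    "partition_core_periphery",
    "layer_composition",
    "annotate_membership",
]


@dataclass
class Subnetwork:
    """Weighted induced subgraph with every edge weight >= weight_floor."""

    graph: nx.Graph
    weight_floor: float
    missing_genes: tuple[str, ...] = ()

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edges(self) -> list[tuple[str, str, float]]:
        return [(u, v, d["weight"]) for u, v, d in self.graph.edges(data=True)]


def extract_subnetwork(
    network: WeightedNetwork,
    selected_genes: Iterable[str],
    weight_floor: float = 0.5,
    prune_isolated: bool = True,
) -> Subnetwork:
    """Induce the subgraph on ``selected_genes``, dropping weak edges.

    Edges below ``weight_floor`` are removed; with ``prune_isolated`` on,
    selected genes left without any retained edge drop out of the node set
    (which is how a 380-gene selection can end up a 367-node network).
    Selected genes absent from the interactome are reported via
    ``missing_genes``, not silently ignored.
    """
    selected = set(selected_genes)
    present = [g for g in network.genes if g in selected]  # network order: deterministic
    missing = tuple(sorted(selected - set(present)))
    idx = [network.index[g] for g in present]
    G = nx.Graph()
    G.add_nodes_from(present)
    if idx:
        sub = sparse.coo_array(network.W.tocsr()[idx][:, idx])
        for i, j, w in zip(sub.row, sub.col, sub.data):
            if i < j and w >= weight_floor:
                G.add_edge(present[i], present[j], weight=float(w))
    if prune_isolated:
        G.remove_nodes_from([v for v, d in list(G.degree()) if d == 0])
    return Subnetwork(graph=G, weight_floor=weight_floor, missing_genes=missing)


@dataclass
class CoreDecomposition:
    """Core number per node, the layer partition, and the maximum core index."""

    core_number: dict[str, int]
    layers: dict[int, frozenset[str]] = field(default=None)  # type: ignore[assignment]
    kmax: int = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.layers is None:
            self.layers = core_layers_from_numbers(self.core_number)
        if self.kmax is None:
            self.kmax = max(self.core_number.values(), default=0)

    def k_core_nodes(self, k: int) -> set[str]:
        """Nodes of the k-core: union of layers l_j for j >= k."""
        return {v for v, c in self.core_number.items() if c >= k}


def k_core_decompose(sub: Subnetwork) -> CoreDecomposition:
    """Core numbers by iterative minimum-degree peeling (unweighted degrees).

    Weights only acted at the extraction stage; the decomposition of the
    thresholded network uses plain edge counts.
    """
    return CoreDecomposition(core_number=dict(nx.core_number(sub.graph)))


def core_layers_from_numbers(core_number: Mapping[str, int]) -> dict[int, frozenset[str]]:
    layers: dict[int, set[str]] = {}
    for v, k in core_number.items():
        layers.setdefault(k, set()).add(v)
    return {k: frozenset(vs) for k, vs in sorted(layers.items())}


def core_layers(dec: CoreDecomposition) -> dict[int, frozenset[str]]:
    """Layer l_k = nodes in the k-core but not the (k+1)-core."""
    return dict(dec.layers)


@dataclass
class CorePeripheryPartition:
    inner: frozenset[str]
    medium: frozenset[str]
    outer: frozenset[str]
    cutpoints: tuple[int, int]

    def label_of(self, node: str) -> str:
        if node in self.inner:
            return "inner"
        if node in self.medium:
            return "medium"
        return "outer"


def partition_core_periphery(
    dec: CoreDecomposition, k_outer_max: int = 10, k_medium_max: int = 35
) -> CorePeripheryPartition:
    """Split nodes into outer (core <= k_outer_max), medium, and inner layers.

    Nodes with core number 0 (isolated in the decomposed graph) fall into
    the outer periphery.
    """
    if not 0 < k_outer_max < k_medium_max:
        raise ValueError(
            f"cutpoints must satisfy 0 < k_outer_max < k_medium_max, "
            f"got ({k_outer_max}, {k_medium_max})"
        )
    outer, medium, inner = set(), set(), set()
    for v, k in dec.core_number.items():
        if k <= k_outer_max:
            outer.add(v)
        elif k <= k_medium_max:
            medium.add(v)
        else:
            inner.add(v)
    return CorePeripheryPartition(
        inner=frozenset(inner),
        medium=frozenset(medium),
        outer=frozenset(outer),
        cutpoints=(k_outer_max, k_medium_max),
    )


def layer_composition(
    dec: CoreDecomposition, tagged_sets: Mapping[str, Iterable[str]]
) -> pd.DataFrame:
    """Count members of each named gene set per core layer.

    Returns a table indexed by layer k with an ``n_nodes`` column and one
    column per tag, supporting summaries like "141 seed genes in the
    network, 16 of them in the inner core".
    """
    tags = {name: set(genes) for name, genes in tagged_sets.items()}
    records = []
    for k in sorted(dec.layers):
        layer = dec.layers[k]
        row: dict[str, object] = {"layer": k, "n_nodes": len(layer)}
        for name, genes in tags.items():
            row[name] = len(layer & genes)
        records.append(row)
    df = pd.DataFrame.from_records(records, columns=["layer", "n_nodes", *tags])
    return df.set_index("layer")


def annotate_membership(
    sub: Subnetwork, reference: Iterable[str], label: str
) -> pd.Series:
    """Boolean per-node flag for membership in a reference gene set."""
    ref = set(reference)
    flags = pd.Series({v: v in ref for v in sub.nodes}, name=label, dtype=bool)
    return flags
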