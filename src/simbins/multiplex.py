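"""Data model and I/O for undirected simple multiplex networks.

A multiplex network is a collection of layers (edge sets of different
relation types) over a single shared node set.  Layers are undirected
simple graphs: no self-loops, no parallel edges, no weights.  Node
identifiers are opaque labels mapped to a dense 0-based index internally;
all public containers use the original labels.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger("simbins.multiplex")

NodeId = str | int
Edge = tuple[NodeId, NodeId]


def canonical_pair(u: NodeId, v: NodeId, index: Mapping[NodeId, int]) -> Edge:
    """Return (u, v) ordered so that index[u] < index[v].

    Raises ``ValueError`` on a self-pair and ``KeyError`` on an unknown node.
    """
    iu, iv = index[u], index[v]
    if iu == iv:
        raise ValueError(f"self-pair ({u!r}, {v!r}) is not a valid node pair")
    return (u, v) if iu < iv else (v, u)


@dataclass(frozen=True)
class LayerAdjacency:
    """Symmetric 0/1 adjacency of one layer over the shared node index."""

    node_ids: tuple[NodeId, ...]
    matrix: np.ndarray  # dense (n, n) float array, symmetric, zero diagonal

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "index", {v: i for i, v in enumerate(self.node_ids)}
        )

    @property
    def n(self) -> int:
        return len(self.node_ids)

    def pair_indices(self, pair: Edge) -> tuple[int, int]:
        return self.index[pair[0]], self.index[pair[1]]


@dataclass
class MultiplexNetwork:
    """Shared node set plus one edge set per layer.

    ``layers`` maps layer name to a set of canonical (u, v) label pairs
    with ``index[u] < index[v]``.
    """

    node_ids: tuple[NodeId, ...]
    layers: dict[str, set[Edge]]
    index: dict[NodeId, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if len(self.layers) < 1:
            raise ValueError("a multiplex network needs at least one layer")
        self.index = {v: i for i, v in enumerate(self.node_ids)}
        if len(self.index) != len(self.node_ids):
            raise ValueError("duplicate node identifiers")
        for name, edges in self.layers.items():
            canon = set()
            for u, v in edges:
                canon.add(canonical_pair(u, v, self.index))
            self.layers[name] = canon

    @property
    def M(self) -> int:
        return len(self.layers)

    @property
    def n(self) -> int:
        return len(self.node_ids)

    def pair(self, u: NodeId, v: NodeId) -> Edge:
        return canonical_pair(u, v, self.index)

    def degree(self, layer: str) -> np.ndarray:
        """Per-node degree vector of one layer over the shared index."""
        deg = np.zeros(self.n, dtype=np.int64)
        for u, v in self.layers[layer]:
            deg[self.index[u]] += 1
            deg[self.index[v]] += 1
        return deg


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _parse_edge_lines(
    lines: Iterable[str], path: str, combined: bool
) -> dict[str, list[Edge]]:
    """Parse whitespace-separated edge lines; weights parsed and discarded."""
    per_layer: dict[str, list[Edge]] = {}
    n_selfloops = 0
    n_weighted = 0
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        min_cols = 3 if combined else 2
        if len(fields) < min_cols or len(fields) > min_cols + 1:
            raise ValueError(
                f"{path}:{lineno}: malformed line {line!r} "
                f"(expected {min_cols} or {min_cols + 1} columns)"
            )
        if combined:
            layer, u, v = fields[0], fields[1], fields[2]
        else:
            layer, u, v = "", fields[0], fields[1]
        if len(fields) == min_cols + 1:
            n_weighted += 1
        if u == v:
            n_selfloops += 1
            continue
        per_layer.setdefault(layer, []).append((u, v))
    if n_selfloops:
        logger.info("%s: dropped %d self-loop line(s)", path, n_selfloops)
    if n_weighted:
        logger.info(
            "%s: ignored weights on %d line(s) (method is unweighted)",
            path,
            n_weighted,
        )
    return per_layer


def load_multiplex_edgelist(
    path: str | Sequence[str], format: str = "combined"
) -> MultiplexNetwork:
    """Load a multiplex network from plain-text edge lists.

    ``format="combined"``: one file, lines ``layer u v [weight]``
    (CoMuNe-style).  ``format="per-layer"``: a sequence of file paths or a
    directory, one two/three-column edge list per layer; layer names are
    the file stems.  Duplicate edges (in either orientation) collapse to
    one; self-loops are dropped with a logged count; weights are ignored.
    """
    if format == "combined":
        if not isinstance(path, (str, os.PathLike)):
            raise ValueError("combined format takes a single file path")
        with open(path) as fh:
            raw_layers = _parse_edge_lines(fh, str(path), combined=True)
    elif format == "per-layer":
        if isinstance(path, (str, os.PathLike)) and os.path.isdir(path):
            paths = sorted(
                os.path.join(path, f)
                for f in os.listdir(path)
                if not f.startswith(".")
            )
        elif isinstance(path, (str, os.PathLike)):
            paths = [str(path)]
        else:
            paths = [str(p) for p in path]
        raw_layers = {}
        for p in paths:
            name = os.path.splitext(os.path.basename(p))[0]
            with open(p) as fh:
                parsed = _parse_edge_lines(fh, p, combined=False)
            raw_layers[name] = parsed.get("", [])
    else:
        raise ValueError(f"unknown format {format!r}")

    nodes: dict[NodeId, None] = {}  # insertion-ordered set
    for edges in raw_layers.values():
        for u, v in edges:
            nodes.setdefault(u)
            nodes.setdefault(v)
    node_ids = tuple(nodes)
    index = {v: i for i, v in enumerate(node_ids)}
    layers: dict[str, set[Edge]] = {}
    for name, edges in raw_layers.items():
        canon = {canonical_pair(u, v, index) for u, v in edges}
        if len(canon) < len(edges):
            logger.info(
                "layer %r: collapsed %d duplicate edge line(s)",
                name,
                len(edges) - len(canon),
            )
        layers[name] = canon
    return MultiplexNetwork(node_ids=node_ids, layers=layers)


def save_multiplex_edgelist(net: MultiplexNetwork, path: str) -> None:
    """Write the network in the combined ``layer u v`` format."""
    with open(path, "w") as fh:
        fh.write("# layer u v\n")
        for name, edges in net.layers.items():
            for u, v in sorted(edges, key=lambda e: (net.index[e[0]], net.index[e[1]])):
                fh.write(f"{name} {u} {v}\n")


# ---------------------------------------------------------------------------
# Derived quantities
# ---------------------------------------------------------------------------

def node_multiplexity(net: MultiplexNetwork) -> float:
    """Fraction of nodes active (degree >= 1) in more than one layer."""
    if net.M < 2:
        raise ValueError("node multiplexity requires at least two layers")
    active_count = np.zeros(net.n, dtype=np.int64)
    for layer in net.layers:
        active_count += net.degree(layer) > 0
    return float(np.count_nonzero(active_count >= 2)) / net.n


def layer_adjacency(
    net: MultiplexNetwork,
    layer: str,
    edge_subset: set[Edge] | None = None,
) -> LayerAdjacency:
    """Dense symmetric adjacency of one layer over the full node index.

    ``edge_subset`` restricts to a subset of that layer's edges (used to
    build adjacency from training edges only); isolated nodes keep their
    zero rows so every layer shares one index.
    """
    edges = net.layers[layer]
    if edge_subset is not None:
        extra = edge_subset - edges
        if extra:
            raise ValueError(
                f"edge_subset contains {len(extra)} edge(s) not in layer {layer!r}"
            )
        edges = edge_subset
    A = np.zeros((net.n, net.n))
    for u, v in edges:
        i, j = net.index[u], net.index[v]
        A[i, j] = 1.0
        A[j, i] = 1.0
    return LayerAdjacency(node_ids=net.node_ids, matrix=A)
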