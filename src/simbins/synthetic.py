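"""Correlated duplex network generator and permutation null model.

Real multiplex networks show link persistence: the same node pair tends
to be connected in several layers, and similarity in one layer correlates
positively with connection in another.  The generator reproduces exactly
the quantity the fused score exploits — trans-layer edge overlap — with
an exact, tunable parameter: the auxiliary layer is drawn from a standard
random-graph model, and a fraction ω of the target layer's edges is
copied from the auxiliary edge set while the rest are sampled from
non-auxiliary pairs.  Realized overlap |E_T ∩ E_A| / m_T therefore equals
ω up to rounding by construction, for every seed.

``rewire_null`` destroys inter-layer correlation while preserving each
layer's internal structure by permuting the node identities of one layer
(the node-to-node inter-layer mapping reshuffle null model).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .multiplex import Edge, MultiplexNetwork, canonical_pair

TARGET_LAYER = "target"
AUX_LAYER = "auxiliary"


@dataclass(frozen=True)
class DuplexSpec:
    """Parameters of a synthetic two-layer network.

    ``overlap`` (ω) is the fraction of target edges copied from the
    auxiliary layer; ``base_model`` draws the auxiliary layer from an
    Erdős–Rényi G(n, m) ("ER") or a Barabási–Albert preferential
    attachment graph ("BA", degree-heterogeneous).
    """

    n: int
    m_target: int
    m_aux: int
    overlap: float
    base_model: str = "ER"
    seed: int = 0

    def __post_init__(self) -> None:
        max_edges = self.n * (self.n - 1) // 2
        if not 0.0 <= self.overlap <= 1.0:
            raise ValueError(f"overlap must be in [0, 1], got {self.overlap}")
        if self.m_target > max_edges or self.m_aux > max_edges:
            raise ValueError("edge count exceeds n(n-1)/2")
        n_shared = int(np.ceil(self.overlap * self.m_target))
        if n_shared > self.m_aux:
            raise ValueError(
                f"overlap requires {n_shared} shared edges but the auxiliary "
                f"layer has only {self.m_aux}"
            )
        if self.m_target - n_shared > max_edges - self.m_aux:
            raise ValueError("not enough non-auxiliary pairs for target edges")
        if self.base_model not in ("ER", "BA"):
            raise ValueError(f"base_model must be 'ER' or 'BA', got {self.base_model!r}")


def _aux_graph(spec: DuplexSpec, rng: np.random.Generator) -> set[tuple[int, int]]:
    nx_seed = int(rng.integers(0, 2**31))
    if spec.base_model == "ER":
        g = nx.gnm_random_graph(spec.n, spec.m_aux, seed=nx_seed)
        edges = {(min(u, v), max(u, v)) for u, v in g.edges()}
    else:  # BA, then adjust to the exact edge count
        m = max(1, round(spec.m_aux / spec.n))
        g = nx.barabasi_albert_graph(spec.n, m, seed=nx_seed)
        edges = {(min(u, v), max(u, v)) for u, v in g.edges()}
        while len(edges) > spec.m_aux:
            drop_idx = rng.integers(0, len(edges))
            edges.discard(sorted(edges)[drop_idx])
        while len(edges) < spec.m_aux:
            u, v = rng.integers(0, spec.n, size=2)
            if u != v:
                edges.add((min(u, v), max(u, v)))
    return edges


def generate_duplex(spec: DuplexSpec) -> MultiplexNetwork:
    """Generate a duplex with exact edge counts and exact realized overlap.

    The target layer holds ``ceil(ω·m_target)`` edges sampled uniformly
    from the auxiliary edge set plus the remainder sampled uniformly from
    non-auxiliary pairs; all layers share the node set 0..n−1.
    """
    rng = np.random.default_rng(spec.seed)
    aux_edges = _aux_graph(spec, rng)
    aux_sorted = sorted(aux_edges)
    n_shared = int(np.ceil(spec.overlap * spec.m_target))
    shared_idx = rng.choice(len(aux_sorted), size=n_shared, replace=False)
    target_edges = {aux_sorted[k] for k in shared_idx}
    n_extra = spec.m_target - n_shared
    while n_extra > 0:
        u, v = rng.integers(0, spec.n, size=2)
        if u == v:
            continue
        e = (min(u, v), max(u, v))
        if e in aux_edges or e in target_edges:
            continue
        target_edges.add(e)
        n_extra -= 1
    return MultiplexNetwork(
        node_ids=tuple(range(spec.n)),
        layers={TARGET_LAYER: target_edges, AUX_LAYER: set(aux_edges)},
    )


def rewire_null(
    net: MultiplexNetwork, layer: str, seed: int | np.random.SeedSequence = 0
) -> MultiplexNetwork:
    """Correlation-destroying control: permute one layer's node identities.

    The layer's degree sequence and internal structure are preserved
    exactly; only its mapping onto the shared node set (and hence its
    correlation with the other layers) is randomized.
    """
    if layer not in net.layers:
        raise KeyError(f"unknown layer {layer!r}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(net.n)
    ids = net.node_ids
    mapping = {ids[i]: ids[perm[i]] for i in range(net.n)}
    layers: dict[str, set[Edge]] = {}
    for name, edges in net.layers.items():
        if name == layer:
            layers[name] = {
                canonical_pair(mapping[u], mapping[v], net.index)
                for u, v in edges
            }
        else:
            layers[name] = set(edges)
    return MultiplexNetwork(node_ids=ids, layers=layers)
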