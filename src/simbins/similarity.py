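"""Structural similarity measures on a single network layer.

Four base measures feed the multiplex fusion pipeline:

* CN  — common neighbours, ``|Γ(x) ∩ Γ(y)|``.
* RA  — resource allocation, ``Σ_{z ∈ Γ(x)∩Γ(y)} 1/|Γ(z)|``.
* ACT — inverse average commute time of a random walker, computed through
  the Moore–Penrose pseudo-inverse of the graph Laplacian; the commute
  denominator ``l⁺_xx + l⁺_yy − 2 l⁺_xy`` equals the effective resistance
  between x and y on connected graphs.
* LPI — local path index, ``A² + ε A³``, which interpolates between CN
  (ε = 0) and longer-path awareness.

Plus the min–max normalization used to turn a target-layer score into a
crude connection probability.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.linalg
import scipy.sparse.csgraph

from .multiplex import Edge, LayerAdjacency

logger = logging.getLogger("simbins.similarity")

DEFAULT_LPI_EPSILON = 1e-4


@dataclass
class SimilarityScores:
    """Per-pair scores of one measure on one adjacency."""

    measure: str
    scores: dict[Edge, float]

    def __getitem__(self, pair: Edge) -> float:
        return self.scores[pair]

    def __len__(self) -> int:
        return len(self.scores)

    def to_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write(f"# measure: {self.measure}\nu\tv\tscore\n")
            for (u, v), s in self.scores.items():
                fh.write(f"{u}\t{v}\t{s:.12g}\n")


@dataclass
class NormalizedScores:
    """Min–max normalized scores in [0, 1], floored away from zero.

    ``floor`` is the value zero-normalized pairs were raised to so that
    log(score) stays finite; see :func:`minmax_normalize`.
    """

    scores: dict[Edge, float]
    min: float
    max: float
    floor: float

    def __getitem__(self, pair: Edge) -> float:
        return self.scores[pair]


def _extract(
    measure: str, M: np.ndarray, adj: LayerAdjacency, pairs
) -> SimilarityScores:
    out = {}
    for pair in pairs:
        i, j = adj.pair_indices(pair)
        out[pair] = float(M[i, j])
    return SimilarityScores(measure=measure, scores=out)


def cn_scores(adj: LayerAdjacency, pairs) -> SimilarityScores:
    """Common-neighbour count for each requested pair."""
    A = adj.matrix
    return _extract("CN", A @ A, adj, pairs)


def ra_scores(adj: LayerAdjacency, pairs) -> SimilarityScores:
    """Resource-allocation index for each requested pair.

    Each common neighbour z contributes 1/deg(z); a common neighbour has
    degree >= 2 by construction, so no division by zero can occur.
    """
    A = adj.matrix
    deg = A.sum(axis=1)
    inv = np.divide(1.0, deg, out=np.zeros_like(deg), where=deg > 0)
    return _extract("RA", A @ (inv[:, None] * A), adj, pairs)


def act_scores(adj: LayerAdjacency, pairs) -> SimilarityScores:
    """Inverse average-commute-time similarity for each requested pair.

    The Laplacian pseudo-inverse is taken spectrally (``pinvh``), which on
    connected graphs coincides with the rank-one-shift inverse
    ``(L − ee'/n)^{-1} + ee'/n`` and stays defined on disconnected graphs.
    A pair split across components has infinite commute time, so its
    similarity is 0.
    """
    A = adj.matrix
    n = adj.n
    if n < 2:
        raise ValueError("ACT needs at least two nodes")
    L = np.diag(A.sum(axis=1)) - A
    try:
        Lp = scipy.linalg.pinvh(L)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - pathological
        raise np.linalg.LinAlgError(
            f"Laplacian pseudo-inverse failed for n={n} adjacency"
        ) from exc
    _, component = scipy.sparse.csgraph.connected_components(
        scipy.sparse.csr_matrix(A), directed=False
    )
    d = np.diag(Lp)
    out = {}
    for pair in pairs:
        i, j = adj.pair_indices(pair)
        if component[i] != component[j]:
            out[pair] = 0.0
            continue
        denom = d[i] + d[j] - 2.0 * Lp[i, j]
        out[pair] = float(1.0 / denom) if denom > 1e-12 else 0.0
    return SimilarityScores(measure="ACT", scores=out)


def lpi_scores(
    adj: LayerAdjacency, pairs, epsilon: float = DEFAULT_LPI_EPSILON
) -> SimilarityScores:
    """Local path index ``(A²)_{xy} + ε (A³)_{xy}`` for each requested pair."""
    if epsilon < 0:
        raise ValueError(f"LPI epsilon must be >= 0, got {epsilon}")
    A = adj.matrix
    A2 = A @ A
    return _extract("LPI", A2 + epsilon * (A2 @ A), adj, pairs)


MEASURES = {
    "CN": cn_scores,
    "RA": ra_scores,
    "ACT": act_scores,
    "LPI": lpi_scores,
}


def compute_scores(
    measure: str,
    adj: LayerAdjacency,
    pairs,
    epsilon: float = DEFAULT_LPI_EPSILON,
) -> SimilarityScores:
    """Dispatch on measure name (CN, RA, ACT, LPI)."""
    measure = measure.upper()
    if measure not in MEASURES:
        raise ValueError(f"unknown similarity measure {measure!r}")
    if measure == "LPI":
        return lpi_scores(adj, pairs, epsilon=epsilon)
    return MEASURES[measure](adj, pairs)


def minmax_normalize(
    scores: SimilarityScores, floor_fraction: float = 0.1
) -> NormalizedScores:
    """Map scores linearly onto [0, 1] over the provided pair set.

    Normalized values strictly below ``floor = floor_fraction × (smallest
    positive normalized value)`` are raised to that floor so the log term
    of the fused score stays finite while ordering among positive scores
    is preserved.  If all scores are equal the map is degenerate and every
    pair gets 1 (logged warning).
    """
    if len(scores) < 2:
        raise ValueError("normalization needs at least two scored pairs")
    values = np.fromiter(scores.scores.values(), dtype=float, count=len(scores))
    lo, hi = float(values.min()), float(values.max())
    if hi == lo:
        logger.warning(
            "degenerate normalization: all %d scores equal %g; mapping to 1",
            len(values),
            hi,
        )
        norm = np.ones_like(values)
        floor = 1.0
    else:
        norm = (values - lo) / (hi - lo)
        positive = norm[norm > 0]
        floor = floor_fraction * float(positive.min())
        norm = np.maximum(norm, floor)
    return NormalizedScores(
        scores=dict(zip(scores.scores.keys(), norm.tolist())),
        min=lo,
        max=hi,
        floor=floor,
    )
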