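"""Fused multiplex link-prediction scores and comparator scorers.

The core score treats link formation as an uncertainty-reduction problem:
the self-information of a pair being linked in the target layer is
estimated from its min–max normalized target similarity, and the mutual
information contributed by knowing the pair's (target-bin, auxiliary-bin)
cell is estimated from empirical bin connection probabilities fused with
the probabilistic OR.  The resulting score, in bits,

    SB(x, y) = log2(s̃_xy) + log2( OR(p_intra(i), p_trans_slice(j)) )

uses the auxiliary-connected trans-layer slice when (x, y) is an edge of
the auxiliary layer and the unconnected slice otherwise.

Alongside the fused score live the baselines (target similarity alone;
plain sum of target and auxiliary similarity) and the relevance-weighted
comparators that blend the two layers with a scalar layer-relevance
weight (edge-overlap GOR or degree-correlation PCC).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.stats

from .binning import BinPartition, PairUniverse, ProbabilityTable
from .multiplex import Edge, MultiplexNetwork
from .similarity import NormalizedScores, SimilarityScores

logger = logging.getLogger("simbins.scoring")

DEFAULT_PHI = 0.5


@dataclass
class ScoredRanking:
    """A method's per-pair scores; higher score = more likely link."""

    method: str
    scores: dict[Edge, float]
    metadata: dict = field(default_factory=dict)

    def __getitem__(self, pair: Edge) -> float:
        return self.scores[pair]

    def __len__(self) -> int:
        return len(self.scores)

    def to_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write(f"# method: {self.method}\n")
            for k, v in sorted(self.metadata.items()):
                fh.write(f"# {k}: {v}\n")
            fh.write("u\tv\tscore\trank\n")
            ordered = sorted(
                self.scores.items(), key=lambda kv: kv[1], reverse=True
            )
            for rank, ((u, v), s) in enumerate(ordered, start=1):
                fh.write(f"{u}\t{v}\t{s:.12g}\t{rank}\n")


# ---------------------------------------------------------------------------
# Decision fusion
# ---------------------------------------------------------------------------

def _check_prob(p: float, name: str) -> None:
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"{name} must be a probability in [0, 1], got {p}")


def or_fuse(p: float, q: float) -> float:
    """Probabilistic OR of two independent opinions: p + q − pq."""
    _check_prob(p, "p")
    _check_prob(q, "q")
    return p + q - p * q


def and_fuse(p: float, q: float) -> float:
    """Probabilistic AND: pq (diagnostic; the fused score uses OR)."""
    _check_prob(p, "p")
    _check_prob(q, "q")
    return p * q


def estimate_connection_probability(
    probs: ProbabilityTable, i: int, j: int, aux_connected: bool
) -> float:
    """OR-fused connection probability for target bin i, auxiliary bin j.

    Uses the auxiliary-connected trans-layer slice when the pair is an
    auxiliary edge, the unconnected slice otherwise.
    """
    trans = probs.p_conn[j] if aux_connected else probs.p_unconn[j]
    intra = probs.p_intra[i]
    if np.isnan(intra) or np.isnan(trans):
        raise RuntimeError(
            f"un-imputed probability reached scoring (bins {i}, {j})"
        )
    return or_fuse(float(intra), float(trans))


# ---------------------------------------------------------------------------
# Fused score
# ---------------------------------------------------------------------------

def simbins_score(
    pair: Edge,
    s_norm: NormalizedScores,
    part_T: BinPartition,
    part_A: BinPartition,
    probs: ProbabilityTable,
    aux_edges: set[Edge],
    target_scores: SimilarityScores | None = None,
    aux_scores: SimilarityScores | None = None,
    universe: PairUniverse | None = None,
) -> float:
    """Raw fused score of one pair, in bits (may be −inf at probability 0).

    Bin indices come from the universe assignment when the pair is in U',
    otherwise from the stored equal-depth boundaries applied to the
    pair's raw scores (``target_scores`` / ``aux_scores`` must then cover
    the pair).
    """
    def _bin(part: BinPartition, raw: SimilarityScores | None) -> int:
        if universe is not None and pair in universe:
            return int(part.assignment[universe.position(pair)])
        if raw is None:
            raise ValueError(
                f"pair {pair} outside the universe needs raw scores to bin"
            )
        return part.assign_score(raw[pair])

    i = _bin(part_T, target_scores)
    j = _bin(part_A, aux_scores)
    p = estimate_connection_probability(probs, i, j, pair in aux_edges)
    s = s_norm[pair]
    if p == 0.0:
        return -np.inf
    return float(np.log2(s) + np.log2(p))


def score_simbins(
    pairs,
    s_norm: NormalizedScores,
    part_T: BinPartition,
    part_A: BinPartition,
    probs: ProbabilityTable,
    aux_edges: set[Edge],
    target_scores: SimilarityScores | None = None,
    aux_scores: SimilarityScores | None = None,
    universe: PairUniverse | None = None,
    metadata: dict | None = None,
) -> ScoredRanking:
    """Fused ranking over a pair set, with −inf scores made rankable.

    Pairs whose fused probability is exactly zero would score −inf; they
    are mapped to (smallest finite score − 1) so rank-based evaluation
    sees ordered finite values, and the count is logged.
    """
    raw = {
        p: simbins_score(
            p, s_norm, part_T, part_A, probs, aux_edges,
            target_scores, aux_scores, universe,
        )
        for p in pairs
    }
    finite = [v for v in raw.values() if np.isfinite(v)]
    n_inf = len(raw) - len(finite)
    if n_inf:
        sentinel = (min(finite) if finite else 0.0) - 1.0
        raw = {p: (v if np.isfinite(v) else sentinel) for p, v in raw.items()}
        logger.info("replaced %d −inf fused score(s) with %g", n_inf, sentinel)
    return ScoredRanking(method="SB", scores=raw, metadata=metadata or {})


def simbins_multi(
    pair: Edge,
    per_layer_artifacts: list[dict],
) -> float:
    """Multi-auxiliary extension: sum of per-auxiliary fused scores.

    Each artifact dict holds the keyword arguments of
    :func:`simbins_score` for one (target, auxiliary) duplex.
    """
    if not per_layer_artifacts:
        raise ValueError("at least one auxiliary layer is required")
    return float(sum(simbins_score(pair, **art) for art in per_layer_artifacts))


# ---------------------------------------------------------------------------
# Baselines
# ---------------------------------------------------------------------------

def score_baseline_target(pairs, target_scores: SimilarityScores) -> ScoredRanking:
    """Rank by raw target-layer similarity alone."""
    return ScoredRanking(
        method="S_T", scores={p: float(target_scores[p]) for p in pairs}
    )


def score_baseline_sum(
    pairs, target_scores: SimilarityScores, aux_scores: SimilarityScores
) -> ScoredRanking:
    """Rank by the plain sum of raw target and auxiliary similarity."""
    return ScoredRanking(
        method="S_T+S_A",
        scores={p: float(target_scores[p]) + float(aux_scores[p]) for p in pairs},
    )


# ---------------------------------------------------------------------------
# Layer relevance and relevance-weighted comparators
# ---------------------------------------------------------------------------

@dataclass
class LayerRelevance:
    measure: str  # "GOR" or "PCC"
    value: float


def gor(
    edges_T: set[Edge], edges_A: set[Edge], form: str = "jaccard"
) -> LayerRelevance:
    """Global link overlap rate between two layers.

    ``form="jaccard"``: |E^T ∩ E^A| / |E^T ∪ E^A| (default);
    ``form="min"``: |E^T ∩ E^A| / min(|E^T|, |E^A|).
    """
    if not edges_T and not edges_A:
        raise ValueError("GOR undefined: both edge sets empty")
    inter = len(edges_T & edges_A)
    if form == "jaccard":
        value = inter / len(edges_T | edges_A)
    elif form == "min":
        denom = min(len(edges_T), len(edges_A))
        value = inter / denom if denom else 0.0
    else:
        raise ValueError(f"unknown GOR form {form!r}")
    return LayerRelevance(measure="GOR", value=float(value))


def pcc_relevance(
    net: MultiplexNetwork, layer_T: str, layer_A: str
) -> LayerRelevance:
    """Pearson correlation of the two layers' degree vectors, clamped at 0.

    A negative relevance would flip the auxiliary ranking in the weighted
    comparator score, so anti-correlation is treated as no relevance.
    """
    if net.n < 3:
        raise ValueError("PCC relevance needs at least 3 shared nodes")
    dT = net.degree(layer_T).astype(float)
    dA = net.degree(layer_A).astype(float)
    if dT.std() == 0 or dA.std() == 0:
        logger.warning(
            "zero-variance degree vector (%s vs %s); relevance set to 0",
            layer_T,
            layer_A,
        )
        return LayerRelevance(measure="PCC", value=0.0)
    r = float(scipy.stats.pearsonr(dT, dA).statistic)
    return LayerRelevance(measure="PCC", value=max(r, 0.0))


def relevance_weighted_score(
    pairs,
    target_scores: SimilarityScores,
    aux_scores: SimilarityScores,
    mu: LayerRelevance,
    phi: float = DEFAULT_PHI,
) -> ScoredRanking:
    """Blend the layers: (1 − φ)·S^T + φ·μ·S^A.

    With μ = GOR this is the edge-overlap-weighted comparator; with
    μ = PCC the degree-correlation-weighted one.
    """
    if not 0.0 <= phi <= 1.0:
        raise ValueError(f"phi must be in [0, 1], got {phi}")
    scores = {
        p: (1.0 - phi) * float(target_scores[p])
        + phi * mu.value * float(aux_scores[p])
        for p in pairs
    }
    return ScoredRanking(
        method=f"weighted-{mu.measure}",
        scores=scores,
        metadata={"phi": phi, "mu": mu.value, "relevance": mu.measure},
    )
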