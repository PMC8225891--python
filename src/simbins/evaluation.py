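"""Train/test splitting, sampled AUC / Precision, and the experiment runner.

Evaluation follows the standard missing-link protocol: the target layer's
edges are split into a 90% training set and a 10% test set; candidates
scored at prediction time are the test edges plus a seeded sample of
non-links twice their number (the 2:1 negative ratio mirrors link
imbalance in sparse networks).  Ranking quality is summarised by

* sampled AUC — the probability, estimated with n independent seeded
  comparisons (n = 10000 by default), that a random test link outscores a
  random sampled non-link, counting ties as half wins; and
* Precision@L — the fraction of test links among the top-L candidates,
  L = |E_test| by default, ties at the cut broken by a seeded shuffle.

``run_experiment`` repeats the whole pipeline (split, universe, bins,
probabilities, scores) over seeded iterations and reports per-method
means and standard errors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import binning, scoring, similarity
from .multiplex import Edge, MultiplexNetwork, layer_adjacency

logger = logging.getLogger("simbins.evaluation")

DEFAULT_TRAIN_RATIO = 0.9
DEFAULT_AUC_SAMPLES = 10_000
DEFAULT_ITERATIONS = 100
METHODS = ("SB", "S_T", "S_T+S_A", "YaoGL", "YaoPL")


@dataclass
class EdgeSplit:
    """Seeded train/test partition of the target layer plus sampled
    non-link test candidates (|Z_test| = 2 |E_test| when available)."""

    E_train: set[Edge]
    E_test: set[Edge]
    Z_test: set[Edge]
    seed: object = None

    @property
    def candidates(self) -> list[Edge]:
        return sorted(self.E_test | self.Z_test, key=repr)


def split_edges(
    net: MultiplexNetwork,
    target: str,
    train_ratio: float = DEFAULT_TRAIN_RATIO,
    seed: int | np.random.SeedSequence = 0,
    negative_ratio: int = binning.DEFAULT_NEGATIVE_RATIO,
) -> EdgeSplit:
    """Uniform seeded split of the target layer's edges.

    ``|E_test| = |E^T| − floor(train_ratio · |E^T|)``; Z_test is sampled
    uniformly from the unordered non-edges of the full target layer, so
    every Z_test pair is disconnected in the training set as well.
    """
    if not 0.0 < train_ratio < 1.0:
        raise ValueError(f"train_ratio must be in (0, 1), got {train_ratio}")
    edges = sorted(
        net.layers[target], key=lambda e: (net.index[e[0]], net.index[e[1]])
    )
    if len(edges) < 10:
        raise ValueError(
            f"target layer {target!r} has {len(edges)} edges; need >= 10"
        )
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(edges))
    n_train = int(np.floor(train_ratio * len(edges)))
    E_train = {edges[k] for k in perm[:n_train]}
    E_test = {edges[k] for k in perm[n_train:]}
    Z_test = set(
        binning.sample_nonlinks(
            net, net.layers[target], negative_ratio * len(E_test), rng
        )
    )
    return EdgeSplit(E_train=E_train, E_test=E_test, Z_test=Z_test, seed=seed)


def auc(
    ranking: scoring.ScoredRanking,
    split: EdgeSplit,
    n: int = DEFAULT_AUC_SAMPLES,
    seed: int | np.random.SeedSequence = 0,
) -> float:
    """Sampled AUC: (n' + 0.5 n'') / n over n independent comparisons.

    Each comparison draws (with replacement) one test link and one
    sampled non-link; n' counts strict wins of the link, n'' ties.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not split.E_test or not split.Z_test:
        raise ValueError("empty test or non-link candidate set")
    pos = np.array([ranking[p] for p in sorted(split.E_test, key=repr)])
    neg = np.array([ranking[p] for p in sorted(split.Z_test, key=repr)])
    rng = np.random.default_rng(seed)
    ps = pos[rng.integers(0, len(pos), size=n)]
    ns = neg[rng.integers(0, len(neg), size=n)]
    wins = int(np.count_nonzero(ps > ns))
    ties = int(np.count_nonzero(ps == ns))
    return (wins + 0.5 * ties) / n


def exhaustive_auc(ranking: scoring.ScoredRanking, split: EdgeSplit) -> float:
    """AUC over all |E_test| × |Z_test| comparisons (the sampled AUC's
    exact counterpart, used for cross-checks)."""
    pos = np.array([ranking[p] for p in sorted(split.E_test, key=repr)])
    neg = np.array([ranking[p] for p in sorted(split.Z_test, key=repr)])
    wins = np.count_nonzero(pos[:, None] > neg[None, :])
    ties = np.count_nonzero(pos[:, None] == neg[None, :])
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


def precision_at_L(
    ranking: scoring.ScoredRanking,
    split: EdgeSplit,
    L: int | None = None,
    seed: int | np.random.SeedSequence = 0,
) -> float:
    """Fraction of test links among the top-L scored candidates.

    Candidates are E_test ∪ Z_test; ties are broken by a seeded uniform
    shuffle before the (stable) sort so the cut is deterministic given
    the seed and unbiased in expectation.
    """
    candidates = split.candidates
    if L is None:
        L = len(split.E_test)
    if not 1 <= L <= len(candidates):
        raise ValueError(f"L={L} out of range 1..{len(candidates)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(candidates))
    shuffled = [candidates[k] for k in order]
    top = sorted(shuffled, key=lambda p: ranking[p], reverse=True)[:L]
    hits = sum(1 for p in top if p in split.E_test)
    return hits / L


# ---------------------------------------------------------------------------
# Single pipeline pass and the experiment runner
# ---------------------------------------------------------------------------

def score_duplex(
    net: MultiplexNetwork,
    target: str,
    auxiliary: str,
    base_measure: str = "RA",
    methods=METHODS,
    seed: int | np.random.SeedSequence = 0,
    *,
    train_ratio: float = DEFAULT_TRAIN_RATIO,
    negative_ratio: int = binning.DEFAULT_NEGATIVE_RATIO,
    b_T: int = binning.DEFAULT_BINS,
    b_A: int = binning.DEFAULT_BINS,
    epsilon: float = similarity.DEFAULT_LPI_EPSILON,
    phi: float = scoring.DEFAULT_PHI,
    floor_fraction: float = 0.1,
    imputation: str = "pls",
    all_pairs: bool = False,
) -> tuple[dict[str, scoring.ScoredRanking], EdgeSplit]:
    """One full pass: split, universe, bins, probabilities, method scores.

    Returns the per-method rankings over the evaluation candidates
    (E_test ∪ Z_test, or every non-training pair under ``all_pairs``)
    together with the split.  Only training-set structure of the target
    layer is ever used for scoring; the auxiliary layer is used in full.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    s_split, s_universe = ss.spawn(2)
    split = split_edges(
        net, target, train_ratio, seed=s_split, negative_ratio=negative_ratio
    )
    universe = binning.build_pair_universe(
        net,
        target,
        split.E_train,
        ratio=negative_ratio,
        seed=s_universe,
        exclude_pairs=split.Z_test,
    )
    if all_pairs:
        ids = net.node_ids
        eval_pairs = [
            (ids[i], ids[j])
            for i in range(net.n)
            for j in range(i + 1, net.n)
            if (ids[i], ids[j]) not in split.E_train
        ]
    else:
        eval_pairs = split.candidates
    scored_pairs = list(dict.fromkeys(universe.pairs + eval_pairs))

    adj_T = layer_adjacency(net, target, edge_subset=split.E_train)
    adj_A = layer_adjacency(net, auxiliary)
    sT = similarity.compute_scores(base_measure, adj_T, scored_pairs, epsilon=epsilon)
    sA = similarity.compute_scores(base_measure, adj_A, scored_pairs, epsilon=epsilon)
    aux_edges = net.layers[auxiliary]

    rankings: dict[str, scoring.ScoredRanking] = {}
    need_fused = "SB" in methods
    if need_fused:
        s_norm = similarity.minmax_normalize(sT, floor_fraction=floor_fraction)
        part_T = binning.equal_depth_bins(sT, universe, b=b_T, layer_tag="target")
        part_A = binning.equal_depth_bins(sA, universe, b=b_A, layer_tag="auxiliary")
        probs = binning.build_probability_table(
            part_T, part_A, universe, aux_edges, imputation=imputation
        )
        rankings["SB"] = scoring.score_simbins(
            eval_pairs, s_norm, part_T, part_A, probs, aux_edges,
            target_scores=sT, aux_scores=sA, universe=universe,
            metadata={
                "target": target, "auxiliary": auxiliary,
                "base_measure": base_measure, "b_T": b_T, "b_A": b_A,
            },
        )
    if "S_T" in methods:
        rankings["S_T"] = scoring.score_baseline_target(eval_pairs, sT)
    if "S_T+S_A" in methods:
        rankings["S_T+S_A"] = scoring.score_baseline_sum(eval_pairs, sT, sA)
    if "YaoGL" in methods:
        mu = scoring.gor(net.layers[target], aux_edges)
        rankings["YaoGL"] = scoring.relevance_weighted_score(
            eval_pairs, sT, sA, mu, phi=phi
        )
    if "YaoPL" in methods:
        mu = scoring.pcc_relevance(net, target, auxiliary)
        rankings["YaoPL"] = scoring.relevance_weighted_score(
            eval_pairs, sT, sA, mu, phi=phi
        )
    unknown = set(methods) - set(METHODS)
    if unknown:
        raise ValueError(f"unknown method(s): {sorted(unknown)}")
    return rankings, split


@dataclass
class EvaluationResult:
    """Per-iteration AUC/Precision rows plus experiment metadata."""

    table: pd.DataFrame  # columns: method, iteration, auc, precision
    metadata: dict = field(default_factory=dict)

    def summary(self) -> pd.DataFrame:
        """Mean and standard error of AUC and Precision per method."""
        g = self.table.groupby("method")
        out = g.agg(
            auc_mean=("auc", "mean"),
            auc_se=("auc", "sem"),
            precision_mean=("precision", "mean"),
            precision_se=("precision", "sem"),
            iterations=("iteration", "count"),
        )
        return out.reset_index()


def run_experiment(
    net: MultiplexNetwork,
    target: str,
    auxiliary: str,
    base_measure: str = "RA",
    methods=METHODS,
    iterations: int = DEFAULT_ITERATIONS,
    seed: int = 0,
    auc_samples: int = DEFAULT_AUC_SAMPLES,
    **pipeline_kwargs,
) -> EvaluationResult:
    """Repeat the full pipeline over seeded iterations.

    Each iteration derives its own seed stream from the master seed via a
    counter-based scheme (SeedSequence spawning), re-splitting edges and
    resampling both negative sets, then scores every requested method and
    records sampled AUC and Precision@|E_test|.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    rows = []
    for it in range(iterations):
        ss = np.random.SeedSequence(entropy=seed, spawn_key=(it,))
        s_pipe, s_auc, s_tie = ss.spawn(3)
        rankings, split = score_duplex(
            net, target, auxiliary, base_measure, methods, seed=s_pipe,
            **pipeline_kwargs,
        )
        for method, ranking in rankings.items():
            rows.append(
                {
                    "method": method,
                    "iteration": it,
                    "auc": auc(ranking, split, n=auc_samples, seed=s_auc),
                    "precision": precision_at_L(ranking, split, seed=s_tie),
                }
            )
    table = pd.DataFrame(rows)
    return EvaluationResult(
        table=table,
        metadata={
            "target": target,
            "auxiliary": auxiliary,
            "base_measure": base_measure,
            "iterations": iterations,
            "seed": seed,
            **pipeline_kwargs,
        },
    )
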