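"""Pair universe construction, equal-depth binning and bin probabilities.

The training pair universe U' mixes the observed training links of the
target layer with a seeded random sample of non-links (default twice as
many, reflecting the link imbalance of sparse real networks).  U' is then
partitioned twice by equal-depth (equal-frequency) binning — once on
target-layer similarity, once on auxiliary-layer similarity — and each
bin yields empirical connection probabilities:

* intra-layer: fraction of a target-similarity bin linked in the target
  training set;
* trans-layer: fraction of an auxiliary-similarity bin linked in the
  target training set, optionally split by auxiliary-layer connectedness.

Ties in similarity force shared bins, so some bins can be empty; their
probabilities are imputed by 1-D penalized least-squares smoothing over
the bin axis (discrete cosine transform formulation, smoothing parameter
by generalized cross-validation), with a linear-interpolation fallback.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.fft import dct, idct
from scipy.optimize import minimize_scalar

from .multiplex import Edge, MultiplexNetwork
from .similarity import SimilarityScores

logger = logging.getLogger("simbins.binning")

DEFAULT_NEGATIVE_RATIO = 2
DEFAULT_BINS = 10


# ---------------------------------------------------------------------------
# Pair universe
# ---------------------------------------------------------------------------

@dataclass
class PairUniverse:
    """The set U' = E_train ∪ Z_train with per-pair target link labels."""

    pairs: list[Edge]
    labels: np.ndarray  # 1 if pair in E_train (target layer), else 0
    n_train_edges: int
    n_negatives: int

    def __post_init__(self) -> None:
        self._index = {p: k for k, p in enumerate(self.pairs)}

    def __len__(self) -> int:
        return len(self.pairs)

    def __contains__(self, pair: Edge) -> bool:
        return pair in self._index

    def position(self, pair: Edge) -> int:
        return self._index[pair]


def sample_nonlinks(
    net: MultiplexNetwork,
    excluded_edges: set[Edge],
    count: int,
    rng: np.random.Generator,
    exclude_pairs: set[Edge] = frozenset(),
) -> list[Edge]:
    """Sample ``count`` distinct unordered node pairs uniformly from
    U − excluded_edges − exclude_pairs.

    Pairs are drawn by rejection from integer codes of the upper triangle;
    if fewer pairs are available than requested, all of them are returned
    with a warning.
    """
    n = net.n
    total = n * (n - 1) // 2
    available = total - len(excluded_edges) - len(exclude_pairs)
    if available < count:
        logger.warning(
            "requested %d non-link pairs but only %d available; using all",
            count,
            available,
        )
        out = []
        for i in range(n):
            for j in range(i + 1, n):
                pair = (net.node_ids[i], net.node_ids[j])
                if pair not in excluded_edges and pair not in exclude_pairs:
                    out.append(pair)
        return out
    chosen: dict[Edge, None] = {}
    # rejection sampling over triangle codes; dense enough in practice
    while len(chosen) < count:
        batch = rng.integers(0, total, size=max(64, 2 * (count - len(chosen))))
        # decode code k -> (i, j), i < j, rows of the upper triangle
        i = (n - 2 - np.floor(
            np.sqrt(-8.0 * batch + 4.0 * n * (n - 1) - 7.0) / 2.0 - 0.5
        )).astype(np.int64)
        j = (batch + i + 1 - (i * (2 * n - i - 1)) // 2).astype(np.int64)
        for ii, jj in zip(i.tolist(), j.tolist()):
            pair = (net.node_ids[ii], net.node_ids[jj])
            if pair in excluded_edges or pair in exclude_pairs or pair in chosen:
                continue
            chosen[pair] = None
            if len(chosen) == count:
                break
    return list(chosen)


def build_pair_universe(
    net: MultiplexNetwork,
    target: str,
    train_edges: set[Edge],
    ratio: int = DEFAULT_NEGATIVE_RATIO,
    seed: int | np.random.SeedSequence = 0,
    exclude_pairs: set[Edge] = frozenset(),
) -> PairUniverse:
    """Build U' = train_edges ∪ Z_train.

    Z_train is a uniform seeded sample of ``ratio × |train_edges|`` pairs
    from U − E^T, where E^T is the *full* target edge set, so no held-out
    test edge can enter the negative sample.  ``exclude_pairs`` removes
    further pairs from the candidate non-links (e.g. an already drawn
    Z_test, keeping the two negative samples disjoint).
    """
    if ratio < 1:
        raise ValueError(f"negative ratio must be >= 1, got {ratio}")
    full_edges = net.layers[target]
    if not train_edges <= full_edges:
        raise ValueError("train_edges must be a subset of the target layer")
    rng = np.random.default_rng(seed)
    negatives = sample_nonlinks(
        net, full_edges, ratio * len(train_edges), rng, exclude_pairs
    )
    pairs = sorted(train_edges, key=lambda e: (net.index[e[0]], net.index[e[1]]))
    pairs += negatives
    labels = np.zeros(len(pairs), dtype=np.int8)
    labels[: len(train_edges)] = 1
    return PairUniverse(
        pairs=pairs,
        labels=labels,
        n_train_edges=len(train_edges),
        n_negatives=len(negatives),
    )


# ---------------------------------------------------------------------------
# Equal-depth binning
# ---------------------------------------------------------------------------

@dataclass
class BinPartition:
    """Equal-depth partition of U' by one layer's similarity scores.

    ``assignment[k]`` is the 0-based bin of ``universe.pairs[k]``.  Ties
    share a bin (the bin containing the tie block's median rank), so some
    bins may be empty.  ``lower_bounds`` holds, for each non-empty bin,
    the smallest member score; it is used to assign bins to pairs scored
    at prediction time that fall outside U'.
    """

    layer_tag: str
    b: int
    assignment: np.ndarray
    counts: np.ndarray
    nonempty_bins: np.ndarray = field(init=False)
    lower_bounds: np.ndarray = field(init=False)
    _score_min: float = field(init=False)
    _score_max: float = field(init=False)

    def attach_bounds(self, scores: np.ndarray) -> None:
        nonempty = np.flatnonzero(self.counts > 0)
        bounds = np.array(
            [scores[self.assignment == bi].min() for bi in nonempty]
        )
        self.nonempty_bins = nonempty
        self.lower_bounds = bounds
        self._score_min = float(scores.min())
        self._score_max = float(scores.max())

    def assign_score(self, score: float) -> int:
        """Bin for an out-of-universe score via the stored boundaries.

        Scores below every boundary map to the first bin, above the
        highest observed score to the last bin; otherwise the non-empty
        bin whose lower bound is the rightmost one not exceeding the
        score.
        """
        if score < self.lower_bounds[0]:
            return 0
        if score > self._score_max:
            return self.b - 1
        k = int(np.searchsorted(self.lower_bounds, score, side="right")) - 1
        return int(self.nonempty_bins[k])


def equal_depth_bins(
    scores: SimilarityScores | np.ndarray,
    universe: PairUniverse,
    b: int = DEFAULT_BINS,
    layer_tag: str = "",
) -> BinPartition:
    """Partition U' into ``b`` equal-frequency bins of one score vector.

    Pairs are ranked ascending by score; rank r (0-based, N pairs) falls
    in bin ``floor(r·b/N)``.  A block of tied scores is assigned as a
    whole to the bin of its median rank, so bins hold approximately equal
    counts except where ties force deviations (and may then be empty).
    """
    N = len(universe)
    if b < 2:
        raise ValueError(f"bin count must be >= 2, got {b}")
    if b > N:
        raise ValueError(f"bin count {b} exceeds universe size {N}")
    if isinstance(scores, SimilarityScores):
        vec = np.array([scores[p] for p in universe.pairs], dtype=float)
    else:
        vec = np.asarray(scores, dtype=float)
        if vec.shape != (N,):
            raise ValueError("score vector does not match universe size")
    order = np.argsort(vec, kind="stable")
    sorted_vals = vec[order]
    assignment = np.empty(N, dtype=np.int64)
    # walk blocks of tied values
    start = 0
    while start < N:
        stop = start
        while stop + 1 < N and sorted_vals[stop + 1] == sorted_vals[start]:
            stop += 1
        median_rank = (start + stop) / 2.0
        bi = min(b - 1, int(median_rank * b // N))
        assignment[order[start : stop + 1]] = bi
        start = stop + 1
    counts = np.bincount(assignment, minlength=b)
    part = BinPartition(layer_tag=layer_tag, b=b, assignment=assignment, counts=counts)
    part.attach_bounds(vec)
    return part


# ---------------------------------------------------------------------------
# Connection probabilities
# ---------------------------------------------------------------------------

def intra_layer_probability(
    part: BinPartition, universe: PairUniverse
) -> np.ndarray:
    """Per-bin fraction of pairs linked in the target training set.

    Empty bins get NaN (to be imputed downstream).
    """
    labels = universe.labels.astype(float)
    linked = np.bincount(part.assignment, weights=labels, minlength=part.b)
    with np.errstate(invalid="ignore"):
        p = np.where(part.counts > 0, linked / np.maximum(part.counts, 1), np.nan)
    return p


@dataclass
class TransLayerSlice:
    """Trans-layer probabilities per auxiliary bin, with the split by
    auxiliary-layer connectedness.  NaN marks empty denominators."""

    p_trans: np.ndarray
    p_conn: np.ndarray
    p_unconn: np.ndarray
    n_conn: np.ndarray
    n_unconn: np.ndarray


def trans_layer_probability(
    part: BinPartition, universe: PairUniverse, aux_edges: set[Edge]
) -> TransLayerSlice:
    """Per-auxiliary-bin probability of target-layer linkage, overall and
    split into auxiliary-connected / auxiliary-unconnected pairs."""
    labels = universe.labels.astype(float)
    conn = np.array([p in aux_edges for p in universe.pairs], dtype=float)
    b = part.b

    def _ratio(num: np.ndarray, den: np.ndarray) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.where(den > 0, num / np.maximum(den, 1), np.nan)

    total = part.counts.astype(float)
    linked = np.bincount(part.assignment, weights=labels, minlength=b)
    n_conn = np.bincount(part.assignment, weights=conn, minlength=b)
    linked_conn = np.bincount(part.assignment, weights=labels * conn, minlength=b)
    n_unconn = total - n_conn
    linked_unconn = linked - linked_conn
    return TransLayerSlice(
        p_trans=_ratio(linked, total),
        p_conn=_ratio(linked_conn, n_conn),
        p_unconn=_ratio(linked_unconn, n_unconn),
        n_conn=n_conn.astype(np.int64),
        n_unconn=n_unconn.astype(np.int64),
    )


# ---------------------------------------------------------------------------
# Imputation of empty bins
# ---------------------------------------------------------------------------

def _smooth_dct(y: np.ndarray, known: np.ndarray) -> np.ndarray:
    """1-D penalized least-squares smoothing of gridded data with missing
    entries: DCT formulation with the smoothing parameter selected by
    generalized cross-validation (Garcia-style smoother)."""
    n = y.size
    w = known.astype(float)
    y0 = np.where(known, y, np.nanmean(y[known]))
    lam = -2.0 + 2.0 * np.cos(np.arange(n) * np.pi / n)  # DCT-II eigenvalues

    def _solve(s: float) -> np.ndarray:
        gamma = 1.0 / (1.0 + s * lam**2)
        z = y0.copy()
        for _ in range(200):
            z_new = idct(gamma * dct(w * (y0 - z) + z, norm="ortho"), norm="ortho")
            if np.max(np.abs(z_new - z)) < 1e-10:
                z = z_new
                break
            z = z_new
        return z

    def _gcv(log10s: float) -> float:
        s = 10.0**log10s
        z = _solve(s)
        resid = (y0 - z)[known]
        rss = float(resid @ resid)
        trace_h = float(np.sum(1.0 / (1.0 + s * lam**2)))
        denom = (1.0 - trace_h / n) ** 2
        if denom <= 0:
            return np.inf
        return rss / (known.sum() * denom)

    res = minimize_scalar(_gcv, bounds=(-6.0, 8.0), method="bounded")
    return _solve(10.0 ** float(res.x))


def _linear_fill(y: np.ndarray, known: np.ndarray) -> np.ndarray:
    idx = np.flatnonzero(known)
    return np.interp(np.arange(y.size), idx, y[idx])  # edge extension built in


def impute_probabilities(
    values: np.ndarray, method: str = "pls"
) -> tuple[np.ndarray, np.ndarray]:
    """Fill NaN entries of a per-bin probability vector.

    ``method="pls"``: penalized least-squares smoothing over the bin axis
    (GCV-selected smoothing parameter); ``"linear"``: linear interpolation
    with edge extension.  Non-missing entries are returned unchanged;
    imputed entries are clamped to [0, 1].  Returns ``(vector, imputed
    mask)``.
    """
    values = np.asarray(values, dtype=float)
    known = ~np.isnan(values)
    if not known.any():
        raise ValueError("cannot impute: all entries missing")
    missing = ~known
    if not missing.any():
        return values.copy(), missing
    if known.sum() == 1:
        filled = np.full_like(values, values[known][0])
    elif method == "pls":
        filled = _smooth_dct(values, known)
    elif method == "linear":
        filled = _linear_fill(values, known)
    else:
        raise ValueError(f"unknown imputation method {method!r}")
    out = values.copy()
    out[missing] = np.clip(filled[missing], 0.0, 1.0)
    return out, missing


# ---------------------------------------------------------------------------
# Probability table (the scoring-path container)
# ---------------------------------------------------------------------------

@dataclass
class ProbabilityTable:
    """Imputed per-bin probabilities feeding the fused score.

    ``p_intra[i]`` for target bins, ``p_trans/p_conn/p_unconn[j]`` for
    auxiliary bins; the ``*_imputed`` masks flag entries that were filled
    rather than counted.
    """

    p_intra: np.ndarray
    p_trans: np.ndarray
    p_conn: np.ndarray
    p_unconn: np.ndarray
    intra_imputed: np.ndarray
    trans_imputed: np.ndarray
    conn_imputed: np.ndarray
    unconn_imputed: np.ndarray

    def to_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("axis\tbin\tprobability\timputed\n")
            for name, vec, mask in [
                ("intra", self.p_intra, self.intra_imputed),
                ("trans", self.p_trans, self.trans_imputed),
                ("trans_connected", self.p_conn, self.conn_imputed),
                ("trans_unconnected", self.p_unconn, self.unconn_imputed),
            ]:
                for k, (v, m) in enumerate(zip(vec, mask)):
                    fh.write(f"{name}\t{k}\t{v:.12g}\t{int(m)}\n")


def build_probability_table(
    part_T: BinPartition,
    part_A: BinPartition,
    universe: PairUniverse,
    aux_edges: set[Edge],
    imputation: str = "pls",
) -> ProbabilityTable:
    """Estimate all per-bin probabilities on U' and impute empty bins.

    The connected/unconnected trans-layer slices are imputed
    independently so both curves are defined on every auxiliary bin.
    """
    p_intra_raw = intra_layer_probability(part_T, universe)
    trans = trans_layer_probability(part_A, universe, aux_edges)
    p_intra, m_intra = impute_probabilities(p_intra_raw, imputation)
    p_trans, m_trans = impute_probabilities(trans.p_trans, imputation)
    p_conn, m_conn = impute_probabilities(trans.p_conn, imputation)
    p_unconn, m_unconn = impute_probabilities(trans.p_unconn, imputation)
    return ProbabilityTable(
        p_intra=p_intra,
        p_trans=p_trans,
        p_conn=p_conn,
        p_unconn=p_unconn,
        intra_imputed=m_intra,
        trans_imputed=m_trans,
        conn_imputed=m_conn,
        unconn_imputed=m_unconn,
    )


def twod_bin_probabilities(
    part_T: BinPartition, part_A: BinPartition, universe: PairUniverse
) -> np.ndarray:
    """Diagnostic b_T × b_A grid of target-link fractions per 2d-bin.

    Cell (i, j) is the linked fraction of pairs falling in target bin i
    and auxiliary bin j; cells with no member pairs are NaN.  This grid
    is for inspection/plotting only — the fused score uses the 1-D
    probability table, not this grid.
    """
    if len(part_T.assignment) != len(universe) or len(part_A.assignment) != len(
        universe
    ):
        raise ValueError("partitions were not built on this universe")
    flat = part_T.assignment * part_A.b + part_A.assignment
    size = part_T.b * part_A.b
    total = np.bincount(flat, minlength=size).astype(float)
    linked = np.bincount(flat, weights=universe.labels.astype(float), minlength=size)
    with np.errstate(invalid="ignore"):
        grid = np.where(total > 0, linked / np.maximum(total, 1), np.nan)
    return grid.reshape(part_T.b, part_A.b)
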