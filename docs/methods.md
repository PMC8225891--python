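# Methods

## Model and assumptions

The package scores unordered node pairs of one layer (the target, T) of an
undirected, unweighted, simple multiplex network, using one auxiliary layer
(A) as side information. The premise is empirical: in most real
multiplexes, a pair's similarity in one layer correlates positively with
its probability of connection in another, and edges persist across layers.
The fused score turns this into an uncertainty estimate. Writing s̃ for the
min–max-normalized target similarity of a pair, i and j for its equal-depth
similarity bins in T and A, and splitting the auxiliary bin's empirical
link probability by the pair's connectedness in A, the score in bits is

    SB(x,y) = log2(s̃_xy) + log2( p̃_intra(i) + p̃_tr(j) − p̃_intra(i)·p̃_tr(j) )

with p̃_tr the auxiliary-connected or auxiliary-unconnected trans-layer
probability as appropriate. The first term estimates the prior
self-information of the link from target similarity alone; the second is
the OR-fusion of two independent "opinions" — connection probability given
the target bin and given the auxiliary bin. The OR operator is preferred
over AND because a single weak opinion should not veto a strong one. The
constant self-information of the base link rate is a global additive shift
and is dropped; both evaluation metrics are rank-based, so this is exact
(covered by a test).

Assumptions worth keeping in mind: pairs inside one (i, j, connectedness)
cell are treated as exchangeable; the two opinions are treated as
independent, which OR-fusion requires; and all probabilities are empirical
frequencies on a 2:1 positive/negative training universe, not on all of U,
so they are calibrated to that sampling ratio rather than to the network's
true link density (rank order, which is all AUC/Precision see, is
unaffected).

## Pipeline

1. Split the target layer's edges 90/10 into train/test (uniform, seeded);
   sample 2·|E_test| non-links of the full target layer as test negatives.
2. Build U′ = E_train ∪ Z_train with |Z_train| = 2·|E_train|, sampled from
   the non-edges of the *full* target layer (so no test positive can be
   labeled negative) and disjoint from Z_test.
3. Compute base similarity on the training adjacency of T and the full
   adjacency of A, for U′ plus all evaluation pairs.
4. Equal-depth bin U′ twice (b_T = b_A = 10); estimate per-bin
   probabilities; impute empty bins.
5. Score the evaluation pairs; compute sampled AUC (n = 10000) and
   Precision@|E_test| per iteration; average over iterations.

The auxiliary layer is always used in full: its edges are observed data,
not prediction targets. Test-set information never enters scoring; a
dedicated test recomputes all scores after deleting test edges from every
input structure and requires bit-identical results.

## Parameters

| parameter | default | role |
|---|---|---|
| train ratio | 0.9 | fraction of target edges used for training |
| negative ratio | 2 | non-links per link in Z_train and Z_test |
| b_T, b_A | 10 | bins per layer; 10–50 works, fewer degrades resolution |
| ε (LPI) | 10⁻⁴ | weight of length-3 walks; 0 reduces LPI to CN |
| φ | 0.5 | layer mixing of the relevance-weighted comparators |
| AUC samples n | 10000 | comparisons in the sampled AUC (error ~ 1/√n) |
| iterations | 100 | independent split/universe repetitions |
| floor fraction | 0.1 | zero-similarity floor, see below |
| imputation | "pls" | penalized least squares; "linear" fallback |

## Numerical and design choices

**Equal-depth ties.** Pairs with identical scores must share a bin
(otherwise membership would depend on sort stability). A tie block goes to
the bin containing its median rank, so heavy ties (e.g. the many RA zeros)
produce one crowded bin and several empty ones — by design; the empty bins
are then imputed. Bin index is non-decreasing in score.

**Out-of-universe pairs.** Evaluation pairs need bins but are mostly
outside U′. They are assigned via the stored bin boundaries (smallest
member score per non-empty bin): below every boundary → first bin, above
the highest observed score → last bin, otherwise the non-empty bin whose
lower bound is the rightmost one not exceeding the score.

**Zero similarity.** log2(0) would send every zero-similarity pair to −∞
and erase the bin term — exactly the pairs for which auxiliary information
matters most. After min–max normalization, values below
0.1 × (smallest positive normalized score) are raised to that floor; this
preserves the ordering of positive scores and keeps zero-similarity pairs
rankable by their bin term.

**Zero fused probability.** If both bin probabilities are exactly 0 the
score is −∞; such pairs are mapped to (smallest finite score − 1), keeping
them jointly worst-ranked without propagating infinities into the metrics.

**Imputation.** Empty bins are filled by 1-D penalized least-squares
smoothing of the probability curve over the bin axis: the discrete-cosine
formulation with a smoothing parameter chosen by generalized
cross-validation, missing entries carrying zero weight. Known entries are
never altered; imputed values are clamped to [0, 1]. With a single known
entry the fill is that constant. A linear-interpolation fallback (with
edge extension) is available. The connected and unconnected trans-layer
slices are imputed independently, since the final score needs both curves
on every bin. Imputation runs inside the scoring path, not just for
diagnostics.

**ACT on disconnected graphs.** The Laplacian pseudo-inverse is computed
spectrally, which coincides with the rank-one-shift inverse on connected
graphs. A pair split across components has infinite commute time, so its
similarity is set to 0 (the naive pseudo-inverse arithmetic would instead
produce spuriously *small* denominators, i.e. high similarity, because the
pseudo-inverse acts per component).

**Normalization pair set.** Min–max normalization is taken over the
currently scored pair set (U′ plus evaluation pairs), the only set the
pipeline ever materializes; scoring all of U would shift min/max slightly
but leaves ranks unchanged.

**Negative resampling.** Z_train and Z_test are redrawn each iteration
from the iteration's seed stream (counter-based SeedSequence spawning), so
iterations are independent and the whole experiment is reproducible from
the master seed.

**Precision ties.** The top-L cut breaks score ties by a seeded uniform
shuffle — deterministic given the seed, unbiased in expectation.

**Relevance measures.** GOR defaults to the Jaccard form
|E^T∩E^A| / |E^T∪E^A| (an overlap-normalized-by-minimum form is
available); PCC is the Pearson correlation of the two layers' degree
vectors over the shared node index, clamped below at 0 — a negative weight
would invert the auxiliary ranking, which a relevance weight is not meant
to do. Both are reasonable standard readings of "link overlap rate" and
"node-feature correlation" rather than reimplementations of any specific
comparator codebase, and both are configurable.

## Synthetic data: what it does and does not show

`generate_duplex` draws the auxiliary layer from G(n, m) (or a
Barabási–Albert graph trimmed/topped-up to the exact edge count, for
degree heterogeneity) and builds the target layer from ⌈ω·m_T⌉ edges
copied from the auxiliary set plus uniformly sampled non-auxiliary edges.
The overlap parameter ω is realized exactly (up to the ceiling) for every
seed, which makes the one quantity the fused score exploits — trans-layer
connectedness correlation — directly controllable and testable.
`rewire_null` permutes one layer's node identities, preserving its degree
sequence while destroying inter-layer alignment.

Two caveats. First, ω = 0 means edge-*disjoint* layers, which is
anti-correlation, not independence: auxiliary connectedness then excludes
target links, a real signal the fused score may legitimately pick up. The
no-information control is the rewired duplex, whose overlap is
hypergeometric. Tests treat the two cases accordingly (one-sided no-harm
bound at ω = 0; two-sided vanishing-gap bound on the rewired control).
Second, the generator produces homogeneous random layers without
clustering, communities, or degree–degree correlations; passing tests
demonstrate that the pipeline recovers controlled edge overlap, not that
it attains any particular accuracy on real networks, whose similarity
structure is far richer. A latent-geometry generator would add
similarity-correlation beyond bare overlap and is a natural extension
point.

Test and validation problem sizes: the overlap-recovery study uses
duplexes with n = 300 and 900 edges per layer, ω ∈ {0, 0.25, 0.5, 0.75,
1}, 20 trials per level with RA as the base measure; oracle checks
(effective resistance, exhaustive AUC) run exhaustively on graphs of ≤ 8
nodes and candidate sets of a few hundred pairs, where brute force is
exact and fast.

## Known limitations

- Unweighted, undirected layers only; no inter-layer coupling edges or
  temporal structure.
- One auxiliary layer per fused score; multiple auxiliaries are combined
  by summing per-duplex scores (`simbins_multi`), which ignores
  redundancy between auxiliaries.
- Probabilities are estimated on a sampled universe; for very sparse or
  very small layers (few hundred edges) bin estimates get noisy and more
  bins are imputed.
- AA, PA, Katz and random-walk base measures are not included; the
  measure interface (`compute_scores`) is the extension point.
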