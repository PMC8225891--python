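# simbins

Link prediction in multiplex networks by information-theoretic similarity
fusion.

Real-world systems — brains, protein interactomes, social and transport
systems — are multiplex: one node set connected by several kinds of edges
(layers). Missing links in one layer (the *target*) can often be predicted
better by also looking at another layer (the *auxiliary*), because in most
real multiplexes the probability of connection in one layer correlates
positively with structural similarity in the others, and the same node pair
tends to be linked in several layers (link persistence). This package is
for network scientists and computational biologists who want a fast,
general-purpose, similarity-based multiplex link predictor plus the full
evaluation protocol around it.

## The method

For a target layer T and auxiliary layer A, a training pair universe
U′ = E<sub>train</sub><sup>T</sup> ∪ Z<sub>train</sub><sup>T</sup> is built
from the observed training links and a random sample of non-links twice
their number. U′ is partitioned twice by equal-depth (equal-frequency)
binning — once on target-layer similarity, once on auxiliary-layer
similarity — and each bin yields empirical connection probabilities:

- p̃<sub>intra</sub>(S<sub>i</sub><sup>T</sup>) — fraction of target-bin i
  linked in the target training set;
- p̃<sub>trans</sub><sup>T</sup>(S<sub>j</sub><sup>A</sup>) — fraction of
  auxiliary-bin j linked in the target training set, split into
  auxiliary-connected and auxiliary-unconnected node pairs.

Empty bins (forced by score ties) are imputed by penalized least-squares
smoothing over the bin axis. The two probabilities are fused with the
probabilistic OR, `OR(p, q) = p + q − pq`, and the final score of a pair
(x, y) with normalized target similarity s̃<sub>xy</sub>, target bin i and
auxiliary bin j is, in bits,

```
SB(x, y) = log2(s̃_xy) + log2( OR(p̃_intra(i), p̃_trans(j | connectedness of (x,y) in A)) )
```

i.e. minus the estimated conditional self-information of the link. Base
similarity measures: common neighbours (CN), resource allocation (RA),
average commute time (ACT, via the Laplacian pseudo-inverse), and the local
path index (LPI, `A² + εA³`, ε = 10⁻⁴).

Alongside the fused score the package implements the baselines S_T (target
similarity alone) and S_T + S_A (plain sum), and relevance-weighted
comparators `(1−φ)·S_T + φ·μ·S_A` with μ either the global link overlap
rate (GOR) or the Pearson correlation of layer degree vectors (PCC).

Evaluation follows the standard protocol: 90/10 train/test split of the
target layer's edges, non-link test candidates sampled at a 2:1 ratio,
sampled AUC over 10 000 comparisons, Precision@|E_test|, averaged over
seeded iterations.

A synthetic generator produces correlated duplexes whose layers share an
exact, tunable fraction ω of edges, together with a node-permutation null
model that destroys inter-layer correlation while preserving each layer's
structure — so every claim is testable without external data.

## Worked example

```python
import simbins as sb

# a 300-node duplex whose layers share 75% of the target's 900 edges
spec = sb.DuplexSpec(n=300, m_target=900, m_aux=900, overlap=0.75, seed=42)
net = sb.generate_duplex(spec)
print("node multiplexity:", round(sb.node_multiplexity(net), 3))

result = sb.run_experiment(
    net, "target", "auxiliary", base_measure="RA",
    methods=("SB", "S_T", "S_T+S_A"), iterations=10, seed=7,
)
print(result.summary().to_string(index=False))
```

prints

```
node multiplexity: 0.993
 method  auc_mean   auc_se  precision_mean  precision_se  iterations
     SB   0.82690 0.010809        0.781111      0.014157          10
    S_T   0.50671 0.005126        0.331111      0.012915          10
S_T+S_A   0.49971 0.006719        0.328889      0.015017          10
```

On an Erdős–Rényi layer the RA similarity alone carries almost no signal
(AUC ≈ 0.5, precision at the 1/3 base rate), but the fused score recovers
the cross-layer overlap and lifts AUC to ≈ 0.83 and precision to ≈ 0.78:
the auxiliary layer, not the target's own structure, is doing the work.

The same run is available from the shell:

```sh
simbins simulate --n 300 --m-target 900 --m-aux 900 --overlap 0.75 --seed 42 --out data/
simbins evaluate --dataset data/duplex.edges --target target --auxiliary auxiliary \
    --base-measure RA --methods SB,S_T --iterations 10 --seed 7 --out results/
```

Real datasets in the common combined multiplex edge-list format
(`layerID nodeID nodeID [weight]`) load directly with
`sb.load_multiplex_edgelist(path)`.

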