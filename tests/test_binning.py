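import numpy as np
import pytest

from simbins import (
    DuplexSpec,
    MultiplexNetwork,
    PairUniverse,
    SimilarityScores,
    build_pair_universe,
    build_probability_table,
    equal_depth_bins,
    generate_duplex,
    impute_probabilities,
    intra_layer_probability,
    trans_layer_probability,
    twod_bin_probabilities,
)


def _universe(pairs, labels):
    labels = np.asarray(labels, dtype=np.int8)
    return PairUniverse(
        pairs=list(pairs),
        labels=labels,
        n_train_edges=int(labels.sum()),
        n_negatives=int((1 - labels).sum()),
    )


def _scores_from(vec, pairs):
    return SimilarityScores("X", dict(zip(pairs, map(float, vec))))


class TestPairUniverse:
    @pytest.fixture
    def net(self):
        return generate_duplex(
            DuplexSpec(n=40, m_target=100, m_aux=100, overlap=0.5, seed=3)
        )

    def test_two_to_one_ratio(self, net):
        train = set(list(net.layers["target"])[:80])
        uni = build_pair_universe(net, "target", train, ratio=2, seed=1)
        assert len(uni) == 3 * 80
        assert uni.labels.sum() == 80

    def test_negatives_avoid_all_target_edges(self, net):
        train = set(list(net.layers["target"])[:80])
        uni = build_pair_universe(net, "target", train, ratio=2, seed=1)
        negatives = {p for p, l in zip(uni.pairs, uni.labels) if l == 0}
        assert not negatives & net.layers["target"]

    def test_exclude_pairs_respected(self, net):
        train = set(list(net.layers["target"])[:80])
        held_out = set(
            build_pair_universe(net, "target", train, ratio=1, seed=9).pairs[80:]
        )
        uni = build_pair_universe(
            net, "target", train, ratio=2, seed=1, exclude_pairs=held_out
        )
        assert not set(uni.pairs) & held_out

    def test_seed_determinism(self, net):
        train = set(list(net.layers["target"])[:80])
        u1 = build_pair_universe(net, "target", train, ratio=2, seed=42)
        u2 = build_pair_universe(net, "target", train, ratio=2, seed=42)
        assert u1.pairs == u2.pairs

    def test_complete_layer_exhausts_nonlinks(self, caplog):
        n = 6
        edges = {(i, j) for i in range(n) for j in range(i + 1, n)}
        net = MultiplexNetwork(node_ids=tuple(range(n)), layers={"T": edges})
        with caplog.at_level("WARNING", logger="simbins.binning"):
            uni = build_pair_universe(net, "T", edges, ratio=2, seed=0)
        assert uni.n_negatives == 0
        assert any("available" in r.message for r in caplog.records)


class TestEqualDepthBins:
    def test_even_split_of_distinct_scores(self):
        pairs = [(0, k + 1) for k in range(10)]
        uni = _universe(pairs, [0] * 10)
        part = equal_depth_bins(_scores_from(range(10), pairs), uni, b=2)
        assert list(part.counts) == [5, 5]

    def test_tie_block_shares_one_bin(self):
        # nine zeros and a single positive with b=10: one giant tie bin,
        # one singleton, eight empty bins
        pairs = [(0, k + 1) for k in range(10)]
        uni = _universe(pairs, [0] * 10)
        vec = [0.0] * 9 + [5.0]
        part = equal_depth_bins(_scores_from(vec, pairs), uni, b=10)
        nonzero = sorted(part.counts[part.counts > 0])
        assert nonzero == [1, 9]
        assert np.count_nonzero(part.counts == 0) == 8

    def test_bin_index_nondecreasing_in_score(self):
        rng = np.random.default_rng(0)
        pairs = [(0, k + 1) for k in range(50)]
        vec = rng.choice([0.0, 1.0, 2.0, 5.0], size=50)
        uni = _universe(pairs, [0] * 50)
        part = equal_depth_bins(_scores_from(vec, pairs), uni, b=7)
        order = np.argsort(vec, kind="stable")
        assert np.all(np.diff(part.assignment[order]) >= 0)

    def test_partition_conservation(self):
        rng = np.random.default_rng(1)
        pairs = [(0, k + 1) for k in range(33)]
        uni = _universe(pairs, [0] * 33)
        part = equal_depth_bins(_scores_from(rng.random(33), pairs), uni, b=5)
        assert part.counts.sum() == len(uni)

    def test_too_many_bins_rejected(self):
        pairs = [(0, 1), (0, 2)]
        uni = _universe(pairs, [0, 0])
        with pytest.raises(ValueError):
            equal_depth_bins(_scores_from([1, 2], pairs), uni, b=3)

    def test_boundary_assignment_for_new_scores(self):
        pairs = [(0, k + 1) for k in range(10)]
        uni = _universe(pairs, [0] * 10)
        part = equal_depth_bins(_scores_from(range(10), pairs), uni, b=2)
        assert part.assign_score(-1.0) == 0  # below everything
        assert part.assign_score(2.0) == 0  # inside lower bin
        assert part.assign_score(7.0) == 1  # inside upper bin
        assert part.assign_score(99.0) == 1  # above everything


class TestProbabilities:
    def test_intra_fraction_per_bin(self):
        pairs = [(0, k + 1) for k in range(10)]
        labels = [0, 0, 0, 0, 0, 1, 1, 1, 0, 1]
        uni = _universe(pairs, labels)
        part = equal_depth_bins(_scores_from(range(10), pairs), uni, b=2)
        p = intra_layer_probability(part, uni)
        assert p[0] == 0.0
        assert p[1] == pytest.approx(0.8)

    def test_weighted_intra_mean_is_exact_link_fraction(self):
        net = generate_duplex(
            DuplexSpec(n=50, m_target=150, m_aux=150, overlap=0.5, seed=4)
        )
        train = set(list(net.layers["target"])[:120])
        uni = build_pair_universe(net, "target", train, ratio=2, seed=5)
        vec = np.random.default_rng(6).random(len(uni))
        part = equal_depth_bins(vec, uni, b=10)
        p = intra_layer_probability(part, uni)
        weighted = np.nansum(p * part.counts) / len(uni)
        assert weighted == pytest.approx(len(train) / len(uni), abs=1e-12)

    def test_trans_split_count_conservation(self):
        net = generate_duplex(
            DuplexSpec(n=50, m_target=150, m_aux=150, overlap=0.5, seed=7)
        )
        train = set(list(net.layers["target"])[:120])
        uni = build_pair_universe(net, "target", train, ratio=2, seed=8)
        vec = np.random.default_rng(9).random(len(uni))
        part = equal_depth_bins(vec, uni, b=10)
        aux = net.layers["auxiliary"]
        t = trans_layer_probability(part, uni, aux)
        for j in range(part.b):
            lhs = 0.0
            if t.n_conn[j]:
                lhs += t.n_conn[j] * t.p_conn[j]
            if t.n_unconn[j]:
                lhs += t.n_unconn[j] * t.p_unconn[j]
            rhs = part.counts[j] * (t.p_trans[j] if part.counts[j] else 0.0)
            assert lhs == pytest.approx(rhs, abs=1e-9)

    def test_empty_conn_slice_flagged(self):
        pairs = [(0, 1), (0, 2), (1, 2), (1, 3)]
        uni = _universe(pairs, [1, 0, 1, 0])
        part = equal_depth_bins(_scores_from([0, 0, 1, 1], pairs), uni, b=2)
        # no pair is an auxiliary edge: connected slice empty everywhere
        t = trans_layer_probability(part, uni, aux_edges=set())
        assert np.isnan(t.p_conn).all()
        assert not np.isnan(t.p_unconn[part.counts > 0]).any()


class TestImputation:
    def test_linear_midpoint(self):
        out, mask = impute_probabilities(
            np.array([0.1, np.nan, 0.3]), method="linear"
        )
        assert out[1] == pytest.approx(0.2)
        assert list(mask) == [False, True, False]

    def test_identity_when_complete(self):
        vec = np.array([0.2, 0.4, 0.9])
        out, mask = impute_probabilities(vec)
        assert np.array_equal(out, vec)
        assert not mask.any()

    def test_edge_extension(self):
        out, _ = impute_probabilities(
            np.array([np.nan, 0.5, 0.5, np.nan]), method="linear"
        )
        assert np.allclose(out, 0.5)

    def test_pls_smoother_fills_within_bounds_and_keeps_known(self):
        vec = np.array([0.0, 0.1, np.nan, 0.35, np.nan, 0.6, 0.8, np.nan, 1.0, 1.0])
        out, mask = impute_probabilities(vec, method="pls")
        known = ~np.isnan(vec)
        assert np.array_equal(out[known], vec[known])
        assert np.all((out >= 0) & (out <= 1))
        # smoothing over a rising curve should fill with rising values
        assert out[2] > 0.05 and out[2] < 0.5

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError):
            impute_probabilities(np.array([np.nan, np.nan]))


class TestTwoDGrid:
    def _setup(self, seed=11):
        net = generate_duplex(
            DuplexSpec(n=50, m_target=150, m_aux=150, overlap=0.5, seed=seed)
        )
        train = set(list(net.layers["target"])[:120])
        uni = build_pair_universe(net, "target", train, ratio=2, seed=seed)
        rng = np.random.default_rng(seed)
        pT = equal_depth_bins(rng.random(len(uni)), uni, b=5)
        pA = equal_depth_bins(rng.random(len(uni)), uni, b=4)
        return net, uni, pT, pA

    def test_marginals_recover_one_d_probabilities(self):
        _, uni, pT, pA = self._setup()
        grid = twod_bin_probabilities(pT, pA, uni)
        # brute-force recount of row marginals
        p_intra = intra_layer_probability(pT, uni)
        for i in range(pT.b):
            counts = np.array(
                [
                    np.count_nonzero((pT.assignment == i) & (pA.assignment == j))
                    for j in range(pA.b)
                ]
            )
            if counts.sum() == 0:
                continue
            row = np.where(counts > 0, np.nan_to_num(grid[i]), 0.0)
            assert np.sum(row * counts) / counts.sum() == pytest.approx(p_intra[i])

    def test_identical_scores_concentrate_on_diagonal(self):
        pairs = [(0, k + 1) for k in range(12)]
        uni = _universe(pairs, [0] * 12)
        vec = np.arange(12.0)
        pT = equal_depth_bins(vec, uni, b=3)
        pA = equal_depth_bins(vec, uni, b=3)
        grid = twod_bin_probabilities(pT, pA, uni)
        off = ~np.eye(3, dtype=bool)
        assert np.isnan(grid[off]).all()

    def test_mismatched_universe_rejected(self):
        _, uni, pT, pA = self._setup()
        other = _universe([(0, 1), (0, 2)], [0, 1])
        with pytest.raises(ValueError):
            twod_bin_probabilities(pT, pA, other)


def test_probability_table_marks_imputed_entries():
    net = generate_duplex(
        DuplexSpec(n=50, m_target=150, m_aux=150, overlap=0.5, seed=13)
    )
    train = set(list(net.layers["target"])[:120])
    uni = build_pair_universe(net, "target", train, ratio=2, seed=13)
    # heavy ties in both score vectors force empty bins
    rng = np.random.default_rng(13)
    vec_T = rng.choice([0.0, 0.0, 0.0, 1.0, 2.0], size=len(uni))
    vec_A = rng.choice([0.0, 0.0, 3.0], size=len(uni))
    pT = equal_depth_bins(vec_T, uni, b=10)
    pA = equal_depth_bins(vec_A, uni, b=10)
    table = build_probability_table(pT, pA, uni, net.layers["auxiliary"])
    for vec in (table.p_intra, table.p_trans, table.p_conn, table.p_unconn):
        assert not np.isnan(vec).any()
    assert table.intra_imputed.any()  # the forced empty bins were filled
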