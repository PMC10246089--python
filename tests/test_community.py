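import numpy as np
import pytest

from coexmux.community import (
    AdjacencyLayers,
    Partition,
    SupraModularity,
    brute_force_max_modularity,
    build_supra_modularity,
    build_supra_modularity_network,
    consensus_partition,
    genlouvain,
    iterated_genlouvain,
    modularity,
    refine_partition,
)


def _supra(b, c_norm=10.0):
    b = np.asarray(b, float)
    nodes = [(f"g{i}", "L") for i in range(b.shape[0])]
    return SupraModularity(order=nodes, B=(b + b.T) / 2, gamma=np.array([1.0]),
                           c_norm=c_norm)


def _random_supra(n, seed, scale=0.3):
    rng = np.random.default_rng(seed)
    m = rng.standard_normal((n, n)) * scale
    return _supra(m)


class TestBuildSupra:
    def test_single_layer_reduces_to_correlation_modularity(self, small_mlc, small_nulls):
        import dataclasses

        single = dataclasses.replace(
            small_mlc,
            layer_names=[small_mlc.layer_names[0]],
            rho=small_mlc.rho[:1],
            omega=np.zeros((small_mlc.n_genes, 1, 1)),
            sample_counts=small_mlc.sample_counts[:1],
            pair_sample_counts=None,
        )
        supra = build_supra_modularity(single, small_nulls[:1], 1.0)
        np.testing.assert_allclose(
            supra.B, small_mlc.rho[0] - small_nulls[0].null_rho, atol=1e-12
        )

    def test_null_equal_input_cancels_intralayer(self, small_mlc, small_nulls):
        # gamma = 1 with the null replaced by the input zeroes every
        # intralayer entry, leaving only the interlayer couplings.
        class FakeNull:
            def __init__(self, rho):
                self.null_rho = rho

        fake = [FakeNull(small_mlc.rho[a]) for a in range(small_mlc.n_layers)]
        supra = build_supra_modularity(small_mlc, fake, 1.0)
        n = small_mlc.n_genes
        for a in range(small_mlc.n_layers):
            block = supra.B[a * n:(a + 1) * n, a * n:(a + 1) * n]
            np.testing.assert_allclose(block, 0.0, atol=1e-12)

    def test_two_gene_two_layer_hand_evaluation(self):
        from coexmux.layers import assemble_multilayer

        rho = np.array([[[1.0, 0.6], [0.6, 1.0]], [[1.0, -0.2], [-0.2, 1.0]]])
        omega = np.zeros((2, 2, 2))
        omega[0, 0, 1] = omega[0, 1, 0] = 0.5
        omega[1, 0, 1] = omega[1, 1, 0] = 0.3
        mlc = assemble_multilayer(rho, omega, ["g0", "g1"], ["A", "B"], [10, 10])

        class FakeNull:
            def __init__(self, c):
                self.null_rho = c

        nulls = [FakeNull(np.array([[1.0, 0.4], [0.4, 1.0]])),
                 FakeNull(np.array([[1.0, -0.2], [-0.2, 1.0]]))]
        supra = build_supra_modularity(mlc, nulls, [2.0, 1.0])
        expected = np.array(
            [
                # (g0,A)   (g1,A)   (g0,B)  (g1,B)
                [1 - 2.0, 0.6 - 0.8, 0.5, 0.0],
                [0.6 - 0.8, 1 - 2.0, 0.0, 0.3],
                [0.5, 0.0, 1 - 1.0, -0.2 + 0.2],
                [0.0, 0.3, -0.2 + 0.2, 1 - 1.0],
            ]
        )
        np.testing.assert_allclose(supra.B, expected, atol=1e-12)
        # C_norm: all rho entries (incl. diagonals) plus all omega entries
        assert supra.c_norm == pytest.approx(rho.sum() + omega.sum())

    def test_gamma_must_be_positive(self, small_mlc, small_nulls):
        with pytest.raises(ValueError):
            build_supra_modularity(small_mlc, small_nulls, 0.0)


class TestNetworkVariant:
    def test_single_layer_newman_girvan(self):
        adj = np.array(
            [[0, 1, 1, 0], [1, 0, 0, 1], [1, 0, 0, 1], [0, 1, 1, 0.0]]
        )
        layers = AdjacencyLayers(
            gene_ids=list("abcd"), layer_names=["L"],
            layers=adj[None], omega=np.zeros((4, 1, 1)),
        )
        supra = build_supra_modularity_network(layers, 1.0)
        k = adj.sum(axis=1)
        expected = adj - np.outer(k, k) / adj.sum()
        np.testing.assert_allclose(supra.B, expected, atol=1e-12)
        # all-in-one partition on a regular graph: null exactly balances edges
        part = Partition(nodes=supra.order, labels=np.ones(4, int))
        assert modularity(part, supra) == pytest.approx(0.0, abs=1e-12)

    def test_zero_omega_gives_block_diagonal(self):
        adj = np.array([[0, 1.0], [1.0, 0]])
        layers = AdjacencyLayers(
            gene_ids=["a", "b"], layer_names=["X", "Y"],
            layers=np.stack([adj, adj]), omega=np.zeros((2, 2, 2)),
        )
        supra = build_supra_modularity_network(layers, 1.0)
        np.testing.assert_allclose(supra.B[:2, 2:], 0.0)

    def test_empty_layer_rejected(self):
        layers = AdjacencyLayers(
            gene_ids=["a", "b"], layer_names=["X"],
            layers=np.zeros((1, 2, 2)), omega=np.zeros((2, 1, 1)),
        )
        with pytest.raises(ValueError):
            build_supra_modularity_network(layers, 1.0)


class TestModularity:
    def test_all_in_one_and_singletons(self):
        supra = _random_supra(5, seed=0)
        ones = Partition(nodes=supra.order, labels=np.ones(5, int))
        assert modularity(ones, supra) == pytest.approx(supra.B.sum() / supra.c_norm)
        single = Partition(nodes=supra.order, labels=np.arange(5) + 1)
        assert modularity(single, supra) == pytest.approx(
            np.trace(supra.B) / supra.c_norm
        )

    def test_matches_brute_force_pair_sum(self):
        supra = _random_supra(4, seed=1)
        labels = np.array([1, 2, 1, 2])
        part = Partition(nodes=supra.order, labels=labels)
        total = sum(
            supra.B[i, j]
            for i in range(4) for j in range(4)
            if labels[i] == labels[j]
        )
        assert modularity(part, supra) == pytest.approx(total / supra.c_norm)

    def test_merge_gain_identity(self):
        # Q(merged) - Q = 2 * (cross-community B sum) / C_norm
        supra = _random_supra(6, seed=2)
        labels = np.array([1, 1, 2, 2, 3, 3])
        part = Partition(nodes=supra.order, labels=labels)
        merged = Partition(nodes=supra.order, labels=np.where(labels == 2, 1, labels))
        cross = supra.B[np.ix_([0, 1], [2, 3])].sum()
        gain = modularity(merged, supra) - modularity(part, supra)
        assert gain == pytest.approx(2 * cross / supra.c_norm)

    def test_relabeling_invariance(self):
        supra = _random_supra(6, seed=3)
        labels = np.array([1, 2, 1, 3, 2, 3])
        part = Partition(nodes=supra.order, labels=labels)
        relabeled = Partition(nodes=supra.order, labels=labels + 10)
        assert modularity(part, supra) == pytest.approx(
            modularity(relabeled, supra)
        )

    def test_partial_partition_rejected(self, small_mlc, small_nulls):
        supra = build_supra_modularity(small_mlc, small_nulls, 1.0)
        bad = Partition(nodes=supra.order[:4], labels=np.ones(4, int))
        with pytest.raises(ValueError):
            modularity(bad, supra)

    def test_diagonal_entries_do_not_change_argmax(self):
        supra = _random_supra(6, seed=4)
        zeroed = SupraModularity(
            order=supra.order,
            B=supra.B - np.diag(np.diag(supra.B)),
            gamma=supra.gamma, c_norm=supra.c_norm,
        )
        p1, _ = brute_force_max_modularity(supra)
        p2, _ = brute_force_max_modularity(zeroed)
        assert p1.same_assignment(p2)


class TestGenLouvain:
    def test_recovers_planted_blocks(self):
        b = -0.1 * np.ones((8, 8))
        b[:4, :4] = 0.5
        b[4:, 4:] = 0.5
        part = genlouvain(_supra(b), seed=0)
        assert part.n_communities == 2
        assert len(set(part.labels[:4])) == 1 and len(set(part.labels[4:])) == 1

    def test_all_negative_off_diagonal_gives_singletons(self):
        b = -np.ones((6, 6))
        np.fill_diagonal(b, 0.3)
        part = genlouvain(_supra(b), seed=1)
        assert part.n_communities == 6

    def test_seed_determinism(self):
        supra = _random_supra(10, seed=5)
        a = genlouvain(supra, seed=9)
        b = genlouvain(supra, seed=9)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_never_beats_brute_force(self):
        for seed in range(10):
            supra = _random_supra(7, seed=seed)
            _, best = brute_force_max_modularity(supra)
            q = modularity(genlouvain(supra, seed=seed), supra)
            assert q <= best + 1e-12


class TestIteratedGenLouvain:
    def test_fixed_point_is_stable(self):
        b = -0.1 * np.ones((8, 8))
        b[:4, :4] = 0.5
        b[4:, 4:] = 0.5
        supra = _supra(b)
        part = iterated_genlouvain(supra, seed=0)
        again = genlouvain(supra, seed=1, init=part)
        assert again.same_assignment(part)

    def test_q_non_decreasing_across_rounds(self):
        supra = _random_supra(12, seed=6)
        rng = np.random.default_rng(0)
        part = genlouvain(supra, seed=int(rng.integers(2**31 - 1)))
        q = modularity(part, supra)
        for _ in range(5):
            part = genlouvain(supra, seed=int(rng.integers(2**31 - 1)), init=part)
            q_next = modularity(part, supra)
            assert q_next >= q - 1e-12
            q = q_next


class TestRefinement:
    def test_splits_bad_merge(self):
        b = -0.1 * np.ones((8, 8))
        b[:4, :4] = 0.5
        b[4:, 4:] = 0.5
        supra = _supra(b)
        merged = Partition(nodes=supra.order, labels=np.ones(8, int))
        refined = refine_partition(supra, merged, seed=0)
        assert refined.n_communities == 2
        assert modularity(refined, supra) > modularity(merged, supra)

    def test_leaves_optimum_alone(self):
        supra = _random_supra(7, seed=7)
        best, q = brute_force_max_modularity(supra)
        refined = refine_partition(supra, best, seed=0)
        assert modularity(refined, supra) == pytest.approx(q)


class TestConsensus:
    def _planted(self):
        b = -0.1 * np.ones((8, 8))
        b[:4, :4] = 0.5
        b[4:, 4:] = 0.5
        return _supra(b)

    def test_unanimous_inputs_returned(self):
        supra = self._planted()
        part = genlouvain(supra, seed=0)
        cons = consensus_partition([part] * 5, supra, seed=1)
        assert cons.same_assignment(part)

    def test_majority_wins_over_outlier(self):
        supra = self._planted()
        majority = genlouvain(supra, seed=0)
        outlier = Partition(nodes=supra.order,
                            labels=np.array([1, 1, 2, 2, 3, 3, 4, 4]))
        cons = consensus_partition([majority] * 19 + [outlier], supra, seed=2)
        assert cons.same_assignment(majority)

    def test_label_permuted_copies_reduce_to_blocks(self):
        supra = self._planted()
        base = np.array([1, 1, 1, 1, 2, 2, 2, 2])
        perms = [base, 3 - base, base + 7]
        parts = [Partition(nodes=supra.order, labels=p) for p in perms]
        cons = consensus_partition(parts, supra, seed=3)
        assert cons.same_assignment(parts[0])

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            consensus_partition([], None, seed=0)


class TestBruteForce:
    def test_two_node_sign_cases(self):
        attract = _supra([[0.2, 0.4], [0.4, 0.2]])
        part, _ = brute_force_max_modularity(attract)
        assert part.n_communities == 1
        repel = _supra([[0.2, -0.4], [-0.4, 0.2]])
        part, _ = brute_force_max_modularity(repel)
        assert part.n_communities == 2

    def test_too_many_nodes_rejected(self):
        with pytest.raises(ValueError):
            brute_force_max_modularity(_random_supra(11, seed=0))
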