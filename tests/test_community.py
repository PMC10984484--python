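import itertools

import numpy as np
import pytest

from covnet.community import (
    Partition,
    ami,
    coclassification,
    gamma_range,
    louvain_signed,
    mrcc,
    partition_quality,
    sample_partition_ensemble,
    signed_modularity_matrix,
)
from covnet.networks import covariance_network


from oracles import exhaustive_optimum


def labels_of(n, groups):
    out = np.zeros(n, dtype=int)
    for c, g in enumerate(groups, 1):
        out[list(g)] = c
    return out


class TestLouvainSigned:
    def test_two_cliques_recovered_and_globally_optimal(self):
        w = np.zeros((8, 8))
        for block in (range(4), range(4, 8)):
            for i, j in itertools.combinations(block, 2):
                w[i, j] = w[j, i] = 1.0
        p = louvain_signed(w, gamma=1.0, seed=0)
        assert p.n_communities == 2
        assert len(set(p.labels[:4])) == 1 and len(set(p.labels[4:])) == 1
        best_q, _ = exhaustive_optimum(w)
        assert partition_quality(w, p.labels) == pytest.approx(best_q, abs=1e-12)

    def test_complete_uniform_network_single_community(self):
        w = np.ones((6, 6))
        np.fill_diagonal(w, 0.0)
        assert louvain_signed(w, gamma=1.0, seed=0).n_communities == 1

    def test_q_at_least_trivial_partitions(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            n = int(rng.integers(5, 10))
            w = rng.uniform(-1, 1, (n, n))
            w = (w + w.T) / 2
            np.fill_diagonal(w, 0.0)
            p = louvain_signed(w, seed=int(rng.integers(2**31)))
            q = partition_quality(w, p.labels)
            q_one = partition_quality(w, np.ones(n, dtype=int))
            q_single = partition_quality(w, np.arange(n))
            assert q >= q_one - 1e-12
            assert q >= q_single - 1e-12

    def test_matches_exhaustive_search_on_small_signed_networks(self):
        # the optimizer-correctness oracle: 50 random instances, <= 8 nodes
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = int(rng.integers(4, 9))
            w = rng.uniform(-1, 1, (n, n))
            w = (w + w.T) / 2
            np.fill_diagonal(w, 0.0)
            gamma = float(rng.uniform(0.5, 1.5))
            best_q, _ = exhaustive_optimum(w, gamma)
            p = louvain_signed(w, gamma=gamma, seed=int(rng.integers(2**31)),
                               n_restarts=10)
            assert partition_quality(w, p.labels, gamma) == pytest.approx(
                best_q, abs=1e-10
            )

    def test_all_zero_network_single_community_with_warning(self):
        with pytest.warns(UserWarning, match="all-zero"):
            p = louvain_signed(np.zeros((5, 5)), seed=0)
        assert p.n_communities == 1


class TestAmi:
    def test_relabeled_partition_gives_one(self):
        regions = tuple(f"r{i}" for i in range(27))
        rng = np.random.default_rng(0)
        labels = rng.integers(1, 5, 27)
        p1 = Partition(regions, labels)
        p2 = Partition(regions, 5 - labels)  # relabeling
        assert ami(p1, p2) == pytest.approx(1.0)

    def test_symmetry(self):
        regions = tuple(f"r{i}" for i in range(27))
        rng = np.random.default_rng(1)
        p1 = Partition(regions, rng.integers(1, 4, 27))
        p2 = Partition(regions, rng.integers(1, 4, 27))
        assert ami(p1, p2) == pytest.approx(ami(p2, p1), abs=1e-12)

    def test_independent_partitions_near_zero(self):
        regions = tuple(f"r{i}" for i in range(1000))
        rng = np.random.default_rng(2)
        p1 = Partition(regions, rng.integers(1, 5, 1000))
        p2 = Partition(regions, rng.integers(1, 5, 1000))
        assert abs(ami(p1, p2)) < 0.05

    def test_region_mismatch_rejected(self):
        p1 = Partition(("a", "b"), [1, 2])
        p2 = Partition(("a", "c"), [1, 2])
        with pytest.raises(ValueError, match="same regions"):
            ami(p1, p2)


class TestCoclassification:
    def test_identical_partitions_binary(self):
        regions = tuple(f"r{i}" for i in range(6))
        p = Partition(regions, [1, 1, 2, 2, 3, 3])
        co, mean = coclassification([p, p, p])
        assert set(np.unique(co)) == {0.0, 1.0}
        assert np.array_equal(co, co.T)
        assert np.all(np.diag(co) == 1.0)

    def test_single_region_flip_counts(self):
        # direct count oracle on a 4-region toy: partitions differ only in r3
        regions = ("r0", "r1", "r2", "r3")
        p1 = Partition(regions, [1, 1, 2, 2])
        p2 = Partition(regions, [1, 1, 2, 1])
        co, mean = coclassification([p1, p2])
        assert co[2, 3] == pytest.approx(0.5)  # together in p1 only
        assert co[0, 3] == pytest.approx(0.5)  # together in p2 only
        assert co[0, 1] == pytest.approx(1.0)
        assert mean[0] == pytest.approx((1.0 + 0.0 + 0.5) / 3)

    def test_fewer_than_two_partitions_rejected(self):
        p = Partition(("a", "b"), [1, 2])
        with pytest.raises(ValueError, match="at least 2"):
            coclassification([p])


class TestMrcc:
    def test_planted_three_modules_recovered(self, modular_table, planted_partition):
        net = covariance_network(modular_table)
        result = mrcc(net, n_partitions=300, alpha=0.05, seed=0)
        truth = Partition(net.region_labels, planted_partition)
        assert ami(result.consensus, truth) == pytest.approx(1.0)

    def test_coassignment_properties(self, modular_table):
        net = covariance_network(modular_table)
        result = mrcc(net, n_partitions=200, alpha=0.05, seed=1)
        co = result.coassignment
        assert np.array_equal(co, co.T)
        assert np.all(np.diag(co) == 1.0)
        assert co.min() >= 0.0 and co.max() <= 1.0
        assert 1 <= result.consensus.n_communities <= 27

    def test_hierarchy_nested_coarse_to_fine(self, modular_table):
        net = covariance_network(modular_table)
        result = mrcc(net, n_partitions=200, alpha=0.05, seed=2)
        ks = [p.n_communities for p in result.hierarchy]
        assert ks[0] == 1
        assert all(a <= b for a, b in zip(ks, ks[1:]))
        # each level refines the previous: same-community pairs never split back
        for coarse, fine in zip(result.hierarchy, result.hierarchy[1:]):
            same_fine = fine.labels[:, None] == fine.labels[None, :]
            same_coarse = coarse.labels[:, None] == coarse.labels[None, :]
            assert np.all(same_fine <= same_coarse)

    def test_deterministic_given_seed(self, modular_table):
        net = covariance_network(modular_table)
        r1 = mrcc(net, n_partitions=150, seed=7)
        r2 = mrcc(net, n_partitions=150, seed=7)
        np.testing.assert_array_equal(r1.consensus.labels, r2.consensus.labels)
        np.testing.assert_array_equal(r1.coassignment, r2.coassignment)

    def test_identical_ensemble_consensus(self):
        # degenerate scale range -> every ensemble member identical ->
        # consensus equals it and coassignment is binary
        w = np.zeros((8, 8))
        for block in (range(4), range(4, 8)):
            for i, j in itertools.combinations(block, 2):
                w[i, j] = w[j, i] = 1.0
        result = mrcc(w, n_partitions=100, seed=3, gammas=(1.0, 1.0))
        assert result.consensus.n_communities == 2
        assert set(np.unique(result.coassignment)) == {0.0, 1.0}

    def test_small_ensemble_rejected(self, modular_table):
        net = covariance_network(modular_table)
        with pytest.raises(ValueError, match="n_partitions"):
            mrcc(net, n_partitions=10, seed=0)

    def test_all_zero_network_degenerate_consensus(self):
        with pytest.warns(UserWarning, match="degenerate"):
            result = mrcc(np.zeros((6, 6)), n_partitions=100, seed=0)
        assert result.consensus.n_communities == 1


class TestGammaRange:
    def test_interval_ordered_and_positive(self, modular_table):
        net = covariance_network(modular_table)
        lo, hi = gamma_range(net.weights)
        assert 0 < lo < hi

    def test_ensemble_spans_scales(self, modular_table):
        net = covariance_network(modular_table)
        rng = np.random.default_rng(0)
        ens = sample_partition_ensemble(net.weights, 150, rng)
        ks = {p.n_communities for p in ens}
        assert min(ks) <= 3 and max(ks) >= 5  # coarse and fine scales present
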