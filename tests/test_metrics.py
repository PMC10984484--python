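import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from covnet.metrics import (
    clustering_signed,
    density,
    identify_hubs,
    nodal_degree,
    nodal_metrics,
    nodal_strength_signed,
)
from covnet.networks import covariance_network, edge_significance, threshold_network


from oracles import brute_force_clustering, random_signed_net


class TestDensityDegreeStrength:
    def test_known_small_network(self):
        w = np.array([[0.0, 0.5, 0.0, -0.3],
                      [0.5, 0.0, 0.2, 0.0],
                      [0.0, 0.2, 0.0, 0.0],
                      [-0.3, 0.0, 0.0, 0.0]])

        class Net:
            weights = w
            region_labels = ("a", "b", "c", "d")

        count, frac = density(Net())
        assert count == 3 and frac == pytest.approx(3 / 6)
        np.testing.assert_array_equal(nodal_degree(Net()), [2, 2, 1, 1])
        s_pos, s_neg = nodal_strength_signed(Net())
        np.testing.assert_allclose(s_pos, [0.5, 0.7, 0.2, 0.0])
        np.testing.assert_allclose(s_neg, [0.3, 0.0, 0.0, 0.3])

    def test_handshake_identity_random(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            w = random_signed_net(int(rng.integers(5, 15)), rng)

            class Net:
                weights = w
                region_labels = tuple(str(i) for i in range(w.shape[0]))

            count, _ = density(Net())
            assert nodal_degree(Net()).sum() == 2 * count

    def test_strength_identity(self):
        rng = np.random.default_rng(1)
        w = random_signed_net(10, rng)

        class Net:
            weights = w
            region_labels = tuple(str(i) for i in range(10))

        s_pos, s_neg = nodal_strength_signed(Net())
        np.testing.assert_allclose(s_pos - s_neg, w.sum(axis=1), atol=1e-12)
        assert np.all(s_pos >= 0) and np.all(s_neg >= 0)


class TestClusteringSigned:
    def test_perfect_positive_triangle(self):
        w = np.full((3, 3), 0.8)
        np.fill_diagonal(w, 0.0)
        np.testing.assert_allclose(clustering_signed(w), 1.0, atol=1e-12)

    def test_star_has_no_triangles(self):
        w = np.zeros((5, 5))
        w[0, 1:] = w[1:, 0] = 0.7
        np.testing.assert_array_equal(clustering_signed(w), 0.0)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            w = random_signed_net(int(rng.integers(3, 7)), rng)
            np.testing.assert_allclose(
                clustering_signed(w), brute_force_clustering(w), atol=1e-12
            )

    def test_bounded_in_unit_interval(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            c = clustering_signed(random_signed_net(12, rng))
            assert np.all(np.abs(c) <= 1 + 1e-12)


class TestHubs:
    def test_exactly_seven_of_27(self):
        rng = np.random.default_rng(2)
        assert len(identify_hubs(rng.random(27), 0.25)) == 7

    def test_all_equal_takes_first_by_index(self):
        np.testing.assert_array_equal(identify_hubs(np.ones(27), 0.25), np.arange(7))

    def test_metric_equal_to_index(self):
        np.testing.assert_array_equal(
            identify_hubs(np.arange(1, 28, dtype=float), 0.25),
            np.array([26, 25, 24, 23, 22, 21, 20]),
        )

    def test_labels_returned_when_given(self):
        labels = [f"r{i}" for i in range(27)]
        out = identify_hubs(np.arange(27, dtype=float), 0.25, region_labels=labels)
        assert list(out) == ["r26", "r25", "r24", "r23", "r22", "r21", "r20"]


class TestMetricProperties:
    @given(seed=st.integers(0, 2**31 - 1), n=st.integers(3, 20))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_signed_strength_decomposition_and_bounds(self, seed, n):
        """s+ - s- equals the plain weighted strength, both parts are
        nonnegative, and degree counts exactly the nonzero edges."""
        w = random_signed_net(n, np.random.default_rng(seed))

        class Net:
            weights = w
            region_labels = tuple(str(i) for i in range(n))

        s_pos, s_neg = nodal_strength_signed(Net())
        assert np.all(s_pos >= 0) and np.all(s_neg >= 0)
        np.testing.assert_allclose(s_pos - s_neg, w.sum(axis=1), atol=1e-12)
        np.testing.assert_array_equal(
            nodal_degree(Net()), np.count_nonzero(w, axis=1)
        )

    @given(seed=st.integers(0, 2**31 - 1), n=st.integers(4, 40),
           q=st.floats(0.05, 1.0))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_hub_count_and_membership(self, seed, n, q):
        """Hubs are always exactly ceil(n*q) distinct regions and contain
        the unique maximum of the metric."""
        import math
        metric = np.random.default_rng(seed).random(n)
        hubs_idx = identify_hubs(metric, q)
        assert len(hubs_idx) == math.ceil(n * q)
        assert len(set(hubs_idx.tolist())) == len(hubs_idx)
        assert int(np.argmax(metric)) in hubs_idx


class TestThresholdMonotonicity:
    def test_degree_and_strength_monotone_in_level(self, modular_table):
        net = covariance_network(modular_table)
        net = net.with_edge_p(edge_significance(modular_table, n_perm=400, seed=9))
        m05 = nodal_metrics(threshold_network(net, 0.05))
        m01 = nodal_metrics(threshold_network(net, 0.01))
        assert np.all(m01.degree <= m05.degree)
        assert np.all(m01.strength_pos <= m05.strength_pos + 1e-12)
        assert np.all(m01.strength_neg <= m05.strength_neg + 1e-12)
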