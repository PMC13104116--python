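"""Network metrics against brute-force oracles and worked examples."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import brute_force_modularity, brute_force_pearson
from craniodyn.network import (
    FunctionalNetwork,
    ModularityParams,
    Partition,
    connectivity_matrix,
    degree_centrality,
    greedy_partition,
    mean_connectivity,
    modularity,
    region_network,
    spectral_partition,
    strong_ratio,
)


def net_from_weights(W):
    return FunctionalNetwork(weights=np.asarray(W, dtype=float),
                             nodes=tuple(range(len(W))))


def two_triangles():
    """Two disjoint unit-weight triangles (nodes 0-2 and 3-5)."""
    W = np.zeros((6, 6))
    for a, b in [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)]:
        W[a, b] = W[b, a] = 1.0
    return net_from_weights(W)


class TestConnectivity:
    @pytest.mark.parametrize(
        "x,y,expected",
        [
            ([1, 2, 3], [2, 4, 6], 1.0),
            ([1, 2, 3], [3, 2, 1], -1.0),
            ([1, 2, 3, 4], [1, 3, 2, 4], 0.8),
        ],
    )
    def test_worked_pairs(self, x, y, expected):
        net = connectivity_matrix(np.array([x, y], dtype=float))
        assert net.weights[0, 1] == pytest.approx(expected, abs=1e-12)
        assert net.weights[1, 0] == net.weights[0, 1]
        assert net.weights[0, 0] == 0.0

    def test_agrees_with_direct_sum_oracle(self):
        rng = np.random.default_rng(42)
        X = rng.standard_normal((10, 50))
        net = connectivity_matrix(X)
        for i in range(10):
            for j in range(i + 1, 10):
                assert net.weights[i, j] == pytest.approx(
                    brute_force_pearson(X[i], X[j]), abs=1e-12)

    def test_zero_variance_series_named(self):
        X = np.array([[1.0, 2.0, 3.0], [5.0, 5.0, 5.0]])
        with pytest.raises(ValueError, match="1"):
            connectivity_matrix(X, nodes=("a", "1"))


class TestScalarMetrics:
    def test_mean_connectivity_examples(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = 0.5
        W[0, 2] = W[2, 0] = 0.7
        W[1, 2] = W[2, 1] = 0.9
        assert mean_connectivity(net_from_weights(W)) == pytest.approx(0.7)
        assert mean_connectivity(net_from_weights(np.zeros((3, 3)))) == 0.0
        # signed mean: {-0.5, 0.5, 0} averages to 0
        W2 = np.zeros((3, 3))
        W2[0, 1] = W2[1, 0] = -0.5
        W2[0, 2] = W2[2, 0] = 0.5
        assert mean_connectivity(net_from_weights(W2)) == pytest.approx(0.0, abs=1e-15)

    def test_strong_ratio_strict_inequality(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = 0.5
        W[0, 2] = W[2, 0] = 0.7
        W[1, 2] = W[2, 1] = 0.9
        assert strong_ratio(net_from_weights(W)) == pytest.approx(1 / 3)
        ties = np.full((3, 3), 0.8)
        np.fill_diagonal(ties, 0.0)
        assert strong_ratio(net_from_weights(ties)) == 0.0
        high = np.full((3, 3), 0.95)
        np.fill_diagonal(high, 0.0)
        assert strong_ratio(net_from_weights(high)) == 1.0


class TestModularity:
    def test_one_community_partition_is_zero(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            n = rng.integers(3, 9)
            W = rng.random((n, n))
            W = np.clip((W + W.T) / 2, 0, 1)
            np.fill_diagonal(W, 0.0)
            net = net_from_weights(W)
            part = Partition(labels=np.zeros(n, dtype=int))
            assert modularity(net, part) == pytest.approx(0.0, abs=1e-12)

    def test_two_triangles_worked_case(self):
        net = two_triangles()
        part = Partition(labels=np.array([0, 0, 0, 1, 1, 1]))
        assert modularity(net, part) == pytest.approx(0.5, abs=1e-12)
        assert modularity(net, part, ModularityParams(gamma=2.0)) == pytest.approx(
            0.0, abs=1e-12)

    def test_matches_brute_force_on_random_graphs(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            n = int(rng.integers(3, 11))
            W = rng.uniform(-1, 1, (n, n))
            W = (W + W.T) / 2
            np.fill_diagonal(W, 0.0)
            net = net_from_weights(W)
            labels = rng.integers(0, 3, n)
            gamma = float(rng.uniform(0.5, 2.0))
            params = ModularityParams(gamma=gamma)
            A = params.transform(net.weights)
            if A.sum() == 0:
                continue
            assert modularity(net, Partition(labels=labels), params) == pytest.approx(
                brute_force_modularity(A, Partition(labels=labels).labels, gamma),
                abs=1e-12)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_permutation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        n = 8
        W = rng.uniform(0, 1, (n, n))
        W = (W + W.T) / 2
        np.fill_diagonal(W, 0.0)
        labels = rng.integers(0, 3, n)
        perm = rng.permutation(n)
        net = net_from_weights(W)
        net_p = net_from_weights(W[np.ix_(perm, perm)])
        q0 = modularity(net, Partition(labels=labels))
        q1 = modularity(net_p, Partition(labels=labels[perm]))
        assert q0 == pytest.approx(q1, abs=1e-12)


class TestDegreeCentrality:
    def test_path_star_and_rowsum(self):
        path = np.zeros((3, 3))
        path[0, 1] = path[1, 0] = path[1, 2] = path[2, 1] = 1.0
        np.testing.assert_allclose(
            degree_centrality(net_from_weights(path)).to_numpy(), [1, 2, 1])
        n = 5
        star = np.zeros((n, n))
        star[0, 1:] = star[1:, 0] = 1.0
        vals = degree_centrality(net_from_weights(star)).to_numpy()
        assert vals[0] == n - 1 and np.all(vals[1:] == 1)
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = 0.2
        W[0, 2] = W[2, 0] = 0.3
        assert degree_centrality(net_from_weights(W)).iloc[0] == pytest.approx(0.5)

    def test_binary_mode_counts_strong_edges(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = 0.9
        W[0, 2] = W[2, 0] = 0.5
        vals = degree_centrality(net_from_weights(W), binary=True)
        np.testing.assert_allclose(vals.to_numpy(), [1, 1, 0])


class TestSpectralPartition:
    def test_planted_two_block_recovery(self):
        rng = np.random.default_rng(3)
        n = 12
        W = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                same = (i < 6) == (j < 6)
                W[i, j] = W[j, i] = 0.9 if same else 0.0
        part = spectral_partition(net_from_weights(W), k=2, seed=0)
        assert len(set(part.labels[:6])) == 1
        assert len(set(part.labels[6:])) == 1
        assert part.labels[0] != part.labels[6]

    def test_k_equals_n_gives_singletons(self):
        net = two_triangles()
        part = spectral_partition(net, k=6, seed=0)
        assert len(set(part.labels)) == 6

    def test_partition_stable_under_node_permutation(self):
        rng = np.random.default_rng(4)
        n = 12
        W = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                same = (i < 6) == (j < 6)
                W[i, j] = W[j, i] = (0.85 if same else 0.05) + rng.uniform(0, 0.05)
        W = np.clip((W + W.T) / 2, -1, 1)
        np.fill_diagonal(W, 0.0)
        perm = rng.permutation(n)
        p0 = spectral_partition(net_from_weights(W), k=2, seed=1).labels
        p1 = spectral_partition(net_from_weights(W[np.ix_(perm, perm)]),
                                k=2, seed=1).labels
        # same partition up to community relabeling
        agree = (p0[perm] == p1).mean()
        assert agree in (0.0, 1.0)

    def test_greedy_partition_recovers_triangles(self):
        net = two_triangles()
        part = greedy_partition(net)
        assert modularity(net, part) == pytest.approx(0.5, abs=1e-12)


class TestRegionNetwork:
    def test_identical_traces_give_unit_weight(self, session, atlas):
        trace = np.sin(np.linspace(0, 40, session.n_frames))
        ds = session.replace(traces=np.tile(trace, (session.n_neurons, 1))
                             + 1e-9 * np.random.default_rng(0).standard_normal(
                                 (session.n_neurons, session.n_frames)))
        net = region_network(ds, atlas)
        assert np.all(net.upper_triangle() > 0.999)

    def test_dropped_region_reported(self, session, atlas):
        # move every neuron out of region 0
        labels = session.regions.copy()
        labels[labels == 0] = 1
        ds = session.replace(regions=labels)
        net = region_network(ds, atlas)
        assert net.meta["dropped"] == [atlas.names[0]]
        assert net.n_nodes == atlas.n_regions - 1

    def test_independent_regions_weakly_correlated(self, atlas):
        import dataclasses

        from craniodyn.synth import (SessionParams, build_schedule,
                                     simulate_session)

        params = dataclasses.replace(
            SessionParams(n_neurons=95), responsive_fraction=0.0,
            within_noise=0.0, between_noise=0.0)
        vals = []
        for seed in range(20):
            ds = simulate_session(params, build_schedule(params, seed=seed),
                                  atlas, seed=seed)
            vals.append(np.abs(region_network(ds, atlas).upper_triangle()).mean())
        assert np.mean(vals) < 0.05
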