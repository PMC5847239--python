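"""Correlation networks, suboptimal paths and community detection."""

import itertools

import networkx as nx
import numpy as np
import pytest

from dimerdyn import synthetic_data as sd
from dimerdyn.core_io import Trajectory
from dimerdyn.network import (
    CorrelationMatrix,
    build_network,
    compare_networks,
    dccm,
    detect_communities,
    node_path_frequency,
    suboptimal_paths,
)


class TestDccm:
    def test_diagonal_symmetry_and_range(self):
        traj = sd.build_two_basin_trajectory(100, 1.0, (0.5, 0.5), seed=0)
        c = dccm(traj, None, superpose=False)
        assert np.allclose(np.diag(c.values), 1.0)
        assert np.allclose(c.values, c.values.T)
        assert np.all(np.abs(c.values) <= 1.0)

    def test_planted_target_recovered(self):
        target = sd.block_correlation_matrix([6, 6], 0.8, 0.2)
        traj = sd.generate_correlated_trajectory(
            sd.CorrelationSpec(target, 1.0, 10000, seed=1), sd.ca_chain(12))
        c = dccm(traj, None, superpose=False)
        assert np.abs(c.values - target).max() < 0.05

    def test_opposite_displacements_give_minus_one(self):
        base = sd.ca_chain(3).coords
        rng = np.random.default_rng(2)
        frames = []
        for _ in range(50):
            d = rng.normal(size=3)
            c = base.copy()
            c[0] += d
            c[1] -= d
            c[2] += rng.normal(size=3)
            frames.append(c)
        c = dccm(Trajectory(np.array(frames)), None, superpose=False)
        assert np.isclose(c.values[0, 1], -1.0, atol=1e-9)

    def test_zero_variance_residue_zeroed_with_warning(self):
        base = sd.ca_chain(4).coords
        rng = np.random.default_rng(3)
        frames = np.repeat(base[None], 30, axis=0)
        frames[:, :3] += rng.normal(0, 1.0, (30, 3, 3))  # residue 3 static
        with pytest.warns(UserWarning, match="zero variance"):
            c = dccm(Trajectory(frames), None, superpose=False)
        assert np.all(c.values[3, :3] == 0.0)
        assert c.values[3, 3] == 1.0


class TestBuildNetwork:
    def test_threshold_is_strict(self):
        vals = np.eye(3)
        vals[0, 1] = vals[1, 0] = 0.4
        vals[1, 2] = vals[2, 1] = 0.41
        net = build_network(CorrelationMatrix(vals, [0, 1, 2]), 0.4)
        assert not net.graph.has_edge(0, 1)
        assert net.graph.has_edge(1, 2)
        assert net.graph.number_of_nodes() == 3  # isolated node kept

    def test_perfect_correlation_gives_zero_weight(self):
        vals = np.eye(2)
        vals[0, 1] = vals[1, 0] = 1.0
        net = build_network(CorrelationMatrix(vals, [0, 1]), 0.4)
        assert net.graph[0][1]["weight"] == 0.0

    def test_negative_correlation_sign_retained(self):
        vals = np.eye(2)
        vals[0, 1] = vals[1, 0] = -0.8
        net = build_network(CorrelationMatrix(vals, [0, 1]), 0.4)
        assert net.graph[0][1]["correlation"] == -0.8
        assert np.isclose(net.graph[0][1]["weight"], -np.log(0.8))

    @pytest.mark.parametrize("seed", range(5))
    def test_random_matrix_edge_set_matches_filter_oracle(self, seed):
        rng = np.random.default_rng(seed)
        raw = rng.uniform(-1, 1, (6, 6))
        vals = (raw + raw.T) / 2
        np.fill_diagonal(vals, 1.0)
        net = build_network(CorrelationMatrix(vals, list(range(6))), 0.4)
        expected = {
            (i, j) for i in range(6) for j in range(i + 1, 6)
            if abs(vals[i, j]) > 0.4
        }
        got = {tuple(sorted(e)) for e in net.graph.edges}
        assert got == expected


def _random_network(seed: int, n_nodes: int):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(5, n_nodes + 1))
    vals = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < 0.45:
                vals[i, j] = vals[j, i] = rng.uniform(0.41, 0.99) * rng.choice([-1, 1])
    np.fill_diagonal(vals, 1.0)
    return build_network(CorrelationMatrix(vals, list(range(n))), 0.4)


def _enumerate_k_shortest(net, source, sink, k):
    g = net.graph
    paths = []
    for p in nx.all_simple_paths(g, source, sink):
        length = sum(g[u][v]["weight"] for u, v in zip(p, p[1:]))
        paths.append((length, p))
    paths.sort(key=lambda t: (t[0], t[1]))
    return paths[:k]


class TestSuboptimalPaths:
    def test_toy_graph_matches_exhaustive_enumeration(self):
        vals = np.eye(4)
        pairs = {(0, 1): 0.9, (1, 3): 0.9, (0, 2): 0.8, (2, 3): 0.8, (0, 3): 0.45}
        for (i, j), v in pairs.items():
            vals[i, j] = vals[j, i] = v
        net = build_network(CorrelationMatrix(vals, list(range(4))), 0.4)
        ps = suboptimal_paths(net, 0, 3, k=3)
        expected = _enumerate_k_shortest(net, 0, 3, 3)
        assert [p for _, p in expected] == ps.paths
        assert np.allclose([l for l, _ in expected], ps.lengths)

    def test_source_equals_sink(self):
        net = _random_network(0, 8)
        ps = suboptimal_paths(net, 0, 0, k=5)
        assert ps.paths == [[0]] and ps.lengths == [0.0]

    def test_k1_is_dijkstra(self):
        net = _random_network(1, 10)
        g = net.graph
        source, sink = 0, max(g.nodes)
        if nx.has_path(g, source, sink):
            ps = suboptimal_paths(net, source, sink, k=1)
            expected = nx.dijkstra_path(g, source, sink, weight="weight")
            expected_len = nx.dijkstra_path_length(g, source, sink, weight="weight")
            assert np.isclose(ps.lengths[0], expected_len)
            assert ps.paths[0] == expected or np.isclose(
                sum(g[u][v]["weight"] for u, v in zip(ps.paths[0], ps.paths[0][1:])),
                expected_len,
            )

    def test_disconnected_pair_flagged(self):
        vals = np.eye(4)
        vals[0, 1] = vals[1, 0] = 0.9
        vals[2, 3] = vals[3, 2] = 0.9
        net = build_network(CorrelationMatrix(vals, list(range(4))), 0.4)
        ps = suboptimal_paths(net, 0, 3, k=5)
        assert ps.status == "disconnected" and ps.paths == []

    def test_lengths_non_decreasing_and_simple(self):
        net = _random_network(2, 12)
        nodes = sorted(net.graph.nodes)
        ps = suboptimal_paths(net, nodes[0], nodes[-1], k=20)
        assert all(b >= a - 1e-12 for a, b in zip(ps.lengths, ps.lengths[1:]))
        assert all(len(set(p)) == len(p) for p in ps.paths)


class TestNodeFrequency:
    def test_single_path_counts_each_node_once(self):
        from dimerdyn.network import PathSet

        ps = PathSet("A", "C", [["A", "B", "C"]], [1.0], 1)
        assert node_path_frequency(ps) == {"A": 1, "B": 1, "C": 1}

    def test_endpoints_occur_in_every_path(self):
        net = _random_network(3, 10)
        nodes = sorted(net.graph.nodes)
        ps = suboptimal_paths(net, nodes[0], nodes[-1], k=10)
        if ps.paths:
            freq = node_path_frequency(ps)
            assert freq[nodes[0]] == len(ps.paths)
            assert freq[nodes[-1]] == len(ps.paths)

    def test_counts_match_brute_force_tally(self):
        from dimerdyn.network import PathSet

        paths = [["a", "b"], ["a", "c", "b"], ["a", "b"], ["a", "d", "b"], ["a", "b"]]
        ps = PathSet("a", "b", paths, [1.0] * 5, 5)
        freq = node_path_frequency(ps)
        tally = {}
        for p in paths:
            for n in p:
                tally[n] = tally.get(n, 0) + 1
        assert freq == tally


class TestCommunities:
    @pytest.mark.parametrize("method", ["walktrap", "girvan_newman"])
    def test_planted_blocks_recovered_exactly(self, method):
        c = CorrelationMatrix(sd.block_correlation_matrix([5, 5], 0.9, 0.1),
                              list(range(10)))
        part = detect_communities(c, 0.5, method)
        groups = sorted(tuple(sorted(v)) for v in part.communities().values())
        assert groups == [(0, 1, 2, 3, 4), (5, 6, 7, 8, 9)]

    def test_uniform_graph_single_community(self):
        vals = np.full((6, 6), 0.9)
        np.fill_diagonal(vals, 1.0)
        part = detect_communities(CorrelationMatrix(vals, list(range(6))), 0.5)
        assert len(part.communities()) == 1

    def test_threshold_above_all_gives_singletons(self):
        vals = np.eye(5)
        vals[0, 1] = vals[1, 0] = 0.3
        part = detect_communities(CorrelationMatrix(vals, list(range(5))), 0.5)
        assert len(part.communities()) == 5
        assert part.modularity == 0.0


class TestCompareNetworks:
    def test_identical_inputs_give_empty_report(self):
        c = CorrelationMatrix(sd.block_correlation_matrix([4, 4]), list(range(8)))
        net = build_network(c, 0.4)
        comm = detect_communities(c, 0.5)
        rep = compare_networks(net, net, comm, comm, c, c)
        assert rep.is_empty
        assert rep.delta_correlation == {}

    def test_single_gained_edge_reported(self):
        vals_apo = np.eye(3)
        vals_holo = vals_apo.copy()
        vals_holo[0, 2] = vals_holo[2, 0] = 0.7
        net_a = build_network(CorrelationMatrix(vals_apo, [0, 1, 2]), 0.4)
        net_h = build_network(CorrelationMatrix(vals_holo, [0, 1, 2]), 0.4)
        rep = compare_networks(net_a, net_h)
        assert rep.gained_edges == [(0, 2)] and rep.lost_edges == []

    def test_split_blocks_match_brute_force_pair_comparison(self):
        c_apo = CorrelationMatrix(sd.block_correlation_matrix([8]), list(range(8)))
        c_holo = CorrelationMatrix(sd.block_correlation_matrix([4, 4]), list(range(8)))
        comm_a = detect_communities(c_apo, 0.5)
        comm_h = detect_communities(c_holo, 0.5)
        rep = compare_networks(build_network(c_apo, 0.4), build_network(c_holo, 0.4),
                               comm_a, comm_h)
        expected_split = {
            tuple(sorted((i, j))) for i, j in itertools.combinations(range(8), 2)
            if (i < 4) != (j < 4)
        }
        assert {tuple(sorted(p)) for p in rep.pairs_split} == expected_split
        assert rep.pairs_joined == []
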