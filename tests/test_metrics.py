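import math

import numpy as np
import pytest

from nnembed.metrics import (
    METRIC_CATEGORIES,
    METRIC_NAMES,
    clustering_coefficient,
    compute_all_metrics,
    hub_set,
    indirect_adjacent_degree,
    nth_neighbor_hub_ratio,
)
from nnembed.netio import DirectedBinaryNetwork
from .conftest import random_digraph

# ---------------------------------------------------------------------------
# Independent brute-force oracle: boolean-reachability distance matrix plus
# direct set arithmetic, sharing no code with the implementation under test.


def oracle_distances(a: np.ndarray) -> np.ndarray:
    n = a.shape[0]
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0)
    reach = np.eye(n, dtype=bool)
    frontier = np.eye(n, dtype=bool)
    for step in range(1, n):
        frontier = (frontier @ (a > 0)) & ~reach
        if not frontier.any():
            break
        d[frontier] = step
        reach |= frontier
    return d


def oracle_hubs(a: np.ndarray, fraction=0.2) -> set:
    deg = a.sum(axis=1)
    h = max(1, math.floor(fraction * len(a)))
    order = sorted(range(len(a)), key=lambda i: (-deg[i], i))
    return set(order[:h])


def oracle_hub_ratio(a, node, n_steps, hubs):
    d = oracle_distances(a)
    shell = {j for j in range(len(a)) if d[node, j] == n_steps}
    if not shell:
        return 0.0
    return len(shell & hubs) / len(shell)


def oracle_iad(a, node):
    d = oracle_distances(a)
    deg = a.sum(axis=1)
    s1 = [j for j in range(len(a)) if d[node, j] == 1]
    s2 = [j for j in range(len(a)) if d[node, j] == 2]
    if not s1 or not s2:
        return 0.0
    d1 = sum(deg[j] for j in s1) / len(s1)
    if d1 == 0:
        return 0.0
    return (sum(deg[j] for j in s2) / len(s2)) / d1


# ---------------------------------------------------------------------------


class TestNewMetricsAgainstOracle:
    def test_agreement_on_200_random_digraphs(self):
        """Both new metrics match BFS-oracle values exactly on random graphs."""
        rng = np.random.default_rng(0)
        for trial in range(200):
            n = int(rng.integers(5, 31))
            density = float(rng.uniform(0.05, 0.5))
            net = random_digraph(n, density, seed=trial)
            a = net.adjacency
            hubs = hub_set(net)
            assert hubs.nodes == frozenset(oracle_hubs(a))
            d = oracle_distances(a)
            for node in range(n):
                got = indirect_adjacent_degree(net, node)
                assert got == pytest.approx(oracle_iad(a, node), abs=1e-12)
                for steps in (1, 2, 3, 4):
                    got_r = nth_neighbor_hub_ratio(net, node, steps, hubs)
                    want = oracle_hub_ratio(a, node, steps, hubs.nodes)
                    assert got_r == pytest.approx(want, abs=1e-12)
                    assert 0.0 <= got_r <= 1.0

    def test_chain_indirect_adjacent_degree(self):
        a = np.zeros((4, 4), int)
        a[0, 1] = a[1, 2] = a[2, 3] = 1
        assert indirect_adjacent_degree(DirectedBinaryNetwork(a), 0) == 1.0

    def test_branching_indirect_adjacent_degree(self):
        a = np.zeros((5, 5), int)
        a[0, 1] = a[1, 2] = a[1, 3] = a[2, 4] = a[3, 4] = 1
        assert indirect_adjacent_degree(DirectedBinaryNetwork(a), 0) == 0.5

    def test_sink_neighbors_empty_distance_two(self):
        a = np.zeros((3, 3), int)
        a[0, 1] = a[0, 2] = 1  # neighbours are sinks
        assert indirect_adjacent_degree(DirectedBinaryNetwork(a), 0) == 0.0

    def test_all_hub_shell_gives_one(self):
        a = np.zeros((5, 5), int)
        a[0, 1] = 1  # node 1 will be the single hub (out-degree below)
        a[1, 2] = a[1, 3] = a[1, 4] = 1
        net = DirectedBinaryNetwork(a)
        hubs = hub_set(net)
        assert hubs.nodes == frozenset({1})
        assert nth_neighbor_hub_ratio(net, 0, 1, hubs) == 1.0

    def test_empty_shell_gives_zero(self, path3):
        hubs = hub_set(path3)
        assert nth_neighbor_hub_ratio(path3, 0, 3, hubs) == 0.0

    def test_forward_backward_coincide_on_symmetric_network(self):
        net = random_digraph(15, 0.3, seed=3)
        sym = DirectedBinaryNetwork(net.adjacency | net.adjacency.T)
        hubs = hub_set(sym)
        for node in range(sym.n_nodes):
            f = indirect_adjacent_degree(sym, node, direction="forward")
            b = indirect_adjacent_degree(sym, node, direction="backward")
            assert f == pytest.approx(b)
            for steps in (1, 2):
                rf = nth_neighbor_hub_ratio(sym, node, steps, hubs, "forward")
                rb = nth_neighbor_hub_ratio(sym, node, steps, hubs, "backward")
                assert rf == pytest.approx(rb)


class TestHubSet:
    def test_two_largest_of_ten_distinct(self):
        a = np.zeros((10, 10), int)
        for i in range(10):  # node i has out-degree i
            a[i, [(i + k + 1) % 10 for k in range(i)]] = 1
        hubs = hub_set(DirectedBinaryNetwork(a))
        assert hubs.nodes == frozenset({8, 9})

    def test_tie_break_by_index_with_warning(self, caplog, cycle3):
        with caplog.at_level("WARNING"):
            hubs = hub_set(cycle3)
        assert hubs.nodes == frozenset({0})
        assert "tie" in caplog.text.lower()

    def test_minimum_one_hub(self):
        net = random_digraph(4, 0.4, seed=0)
        assert len(hub_set(net).nodes) == 1  # floor(0.8) = 0 -> minimum rule


class TestClusteringCoefficient:
    def test_triangle_is_one(self, cycle3):
        # directed 3-cycle projects to an undirected triangle
        assert clustering_coefficient(cycle3, 0) == 1.0

    def test_star_center_is_zero(self):
        a = np.zeros((5, 5), int)
        a[0, 1:] = 1
        assert clustering_coefficient(DirectedBinaryNetwork(a), 0) == 0.0

    def test_one_link_among_three_neighbors(self):
        a = np.zeros((4, 4), int)
        a[0, 1] = a[0, 2] = a[0, 3] = 1
        a[1, 2] = 1  # one link among the neighbours
        got = clustering_coefficient(DirectedBinaryNetwork(a), 0)
        assert got == pytest.approx(2 * 1 / (3 * 2))

    def test_degree_below_two_is_zero(self, path3):
        assert clustering_coefficient(path3, 0) == 0.0

    def test_clique_one_tree_zero(self):
        k5 = DirectedBinaryNetwork((np.ones((5, 5)) - np.eye(5)).astype(int))
        assert all(clustering_coefficient(k5, i) == 1.0 for i in range(5))
        tree = np.zeros((7, 7), int)
        for child in range(1, 7):
            parent = (child - 1) // 2
            tree[parent, child] = 1
        tnet = DirectedBinaryNetwork(tree)
        assert all(clustering_coefficient(tnet, i) == 0.0 for i in range(7))


class TestStandardMetrics:
    def test_cycle_degrees_and_degenerate_clustering(self, cycle3):
        table = compute_all_metrics(cycle3).values
        assert (table["out_degree"] == 1).all()
        assert (table["in_degree"] == 1).all()

    def test_path_betweenness_counts_the_middle_node(self, path3):
        table = compute_all_metrics(path3).values
        assert table["betweenness"].iloc[1] == 1.0
        assert table["betweenness"].iloc[0] == 0.0

    def test_complete_k4_core_number_three(self):
        k4 = DirectedBinaryNetwork((np.ones((4, 4)) - np.eye(4)).astype(int))
        assert (compute_all_metrics(k4).values["core_number"] == 3).all()

    def test_subgraph_centrality_matches_expm_diagonal(self):
        from scipy.linalg import expm

        net = random_digraph(12, 0.3, seed=5)
        table = compute_all_metrics(net).values
        np.testing.assert_allclose(
            table["subgraph_centrality"],
            expm(net.adjacency.astype(float)).diagonal(),
        )

    def test_local_efficiency_unreachable_contributes_zero(self, path3):
        table = compute_all_metrics(path3).values
        # node a: d(a,b)=1, d(a,c)=2 -> (1 + 0.5)/2
        assert table["local_efficiency"].iloc[0] == pytest.approx(0.75)
        # node c reaches nobody forward
        assert table["local_efficiency"].iloc[2] == 0.0


class TestFullTable:
    def test_shape_categories_and_finiteness(self):
        net = random_digraph(40, 0.1, seed=7)
        table = compute_all_metrics(net)
        assert table.values.shape == (40, 15)
        assert list(table.values.columns) == list(METRIC_NAMES)
        assert table.category_counts() == {
            "centrality": 7, "noncentrality": 3, "new": 5,
        }
        assert np.isfinite(table.values.to_numpy()).all()

    def test_symmetric_network_out_equals_in_degree(self):
        net = random_digraph(20, 0.2, seed=8)
        sym = DirectedBinaryNetwork(net.adjacency | net.adjacency.T)
        table = compute_all_metrics(sym).values
        np.testing.assert_array_equal(table["out_degree"], table["in_degree"])

    def test_categories_constant_mapping(self):
        assert set(METRIC_CATEGORIES.values()) == {"centrality", "noncentrality", "new"}
        assert len(METRIC_CATEGORIES) == 15
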