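"""Topological features vs. hand computations, brute force, and networkx."""

import networkx as nx
import numpy as np
import pytest

from netpharm import (
    InteractionNetwork,
    betweenness_map,
    closeness_map,
    core_number_map,
    degree_map,
    feature_median,
    topology_profile,
)
from oracles import brute_betweenness, brute_closeness, brute_core_numbers


def build(nodes, edges):
    net = InteractionNetwork()
    for n in nodes:
        net.add_node(n)
    for u, v in edges:
        net.add_edge(u, v)
    return net


def random_net(rng, n_max=8):
    n = int(rng.integers(2, n_max + 1))
    p = float(rng.uniform(0.05, 0.95))
    nodes = [f"n{i}" for i in range(n)]
    edges = [(a, b) for i, a in enumerate(nodes) for b in nodes[i + 1:]
             if rng.random() < p]
    return nodes, edges


class TestDegree:
    def test_path(self):
        net = build("abc", [("a", "b"), ("b", "c")])
        assert degree_map(net) == {"a": 1, "b": 2, "c": 1}

    def test_complete_graph(self):
        net = build("abcd", [(u, v) for i, u in enumerate("abcd") for v in "abcd"[i + 1:]])
        assert set(degree_map(net).values()) == {3}

    def test_isolated(self):
        net = build("a", [])
        assert degree_map(net) == {"a": 0}


class TestBetweenness:
    def test_path_interior_vertex(self):
        net = build("abc", [("a", "b"), ("b", "c")])
        assert betweenness_map(net) == {"a": 0.0, "b": 1.0, "c": 0.0}

    def test_star_center_counts_all_leaf_pairs(self):
        leaves = [f"l{i}" for i in range(5)]
        net = build(["hub"] + leaves, [("hub", l) for l in leaves])
        assert betweenness_map(net)["hub"] == pytest.approx(10.0)  # C(5,2)

    def test_four_cycle_split_pairs(self):
        net = build("abcd", [("a", "b"), ("b", "c"), ("c", "d"), ("d", "a")])
        # each antipodal pair has 2 shortest paths, each interior vertex gets 1/2
        assert all(v == pytest.approx(0.5) for v in betweenness_map(net).values())


class TestCloseness:
    def test_complete_graph(self):
        net = build("abcd", [(u, v) for i, u in enumerate("abcd") for v in "abcd"[i + 1:]])
        assert all(v == pytest.approx(1 / 3) for v in closeness_map(net).values())

    def test_path_distance_sums(self):
        net = build("abc", [("a", "b"), ("b", "c")])
        clo = closeness_map(net)
        assert clo["b"] == pytest.approx(0.5)
        assert clo["a"] == pytest.approx(1 / 3)

    def test_reachable_only_convention(self):
        net = build("abcd", [("a", "b"), ("c", "d")])
        assert all(v == pytest.approx(1.0) for v in closeness_map(net).values())

    def test_isolated_node_is_zero(self):
        net = build("ab", [])
        assert closeness_map(net) == {"a": 0.0, "b": 0.0}


class TestCoreNumbers:
    def test_triangle(self):
        net = build("abc", [("a", "b"), ("b", "c"), ("a", "c")])
        assert set(core_number_map(net).values()) == {2}

    def test_pendant_peels_first(self):
        net = build("abcp", [("a", "b"), ("b", "c"), ("a", "c"), ("c", "p")])
        core = core_number_map(net)
        assert core["p"] == 1
        assert core["a"] == core["b"] == core["c"] == 2

    def test_edgeless(self):
        net = build("ab", [])
        assert core_number_map(net) == {"a": 0, "b": 0}

    def test_invariant_under_edge_order(self):
        rng = np.random.default_rng(5)
        nodes, edges = random_net(rng)
        expected = core_number_map(build(nodes, edges))
        for _ in range(5):
            perm = [edges[i] for i in rng.permutation(len(edges))]
            assert core_number_map(build(nodes, perm)) == expected

    def test_adding_edge_never_decreases_degree_or_core(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            nodes, edges = random_net(rng)
            net = build(nodes, edges)
            non_edges = [(a, b) for i, a in enumerate(nodes) for b in nodes[i + 1:]
                         if not net.has_edge(a, b)]
            if not non_edges:
                continue
            extra = non_edges[int(rng.integers(len(non_edges)))]
            bigger = build(nodes, edges + [extra])
            for n in nodes:
                assert bigger.degree(n) >= net.degree(n)
                assert core_number_map(bigger)[n] >= core_number_map(net)[n]


class TestMedian:
    @pytest.mark.parametrize("values,expected", [
        ([1, 2, 3], 2.0),
        ([1, 2, 3, 4], 2.5),
        ([5], 5.0),
    ])
    def test_interpolated(self, values, expected):
        assert feature_median(values) == expected

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            feature_median([])


class TestProfile:
    def test_four_cycle_hand_computation(self):
        net = build("abcd", [("a", "b"), ("b", "c"), ("c", "d"), ("d", "a")])
        profile = topology_profile(net)
        for n in "abcd":
            assert profile.degree[n] == 2
            assert profile.betweenness[n] == pytest.approx(0.5)
            assert profile.closeness[n] == pytest.approx(0.25)
            assert profile.kcore[n] == 2
        assert profile.medians == {
            "degree": 2.0, "betweenness": 0.5, "closeness": 0.25, "kcore": 2.0}

    def test_single_edge(self):
        profile = topology_profile(build("ab", [("a", "b")]))
        for n in "ab":
            assert (profile.degree[n], profile.betweenness[n],
                    profile.closeness[n], profile.kcore[n]) == (1, 0.0, 1.0, 1)

    def test_empty_network_raises(self):
        with pytest.raises(ValueError):
            topology_profile(InteractionNetwork())

    def test_tsv_export_columns(self, tmp_path):
        profile = topology_profile(build("ab", [("a", "b")]))
        path = tmp_path / "profile.tsv"
        profile.to_tsv(path)
        header = path.read_text().splitlines()[0].split("\t")
        assert header == ["id", "degree", "betweenness", "closeness", "kcore"]


class TestOracleEquivalence:
    """Exhaustive enumeration agrees with the implementations on random graphs."""

    def test_brute_force_agreement_small_graphs(self):
        rng = np.random.default_rng(2024)
        for _ in range(60):
            nodes, edges = random_net(rng)
            net = build(nodes, edges)
            btw, clo, core = betweenness_map(net), closeness_map(net), core_number_map(net)
            bf_btw = brute_betweenness(nodes, edges)
            bf_clo = brute_closeness(nodes, edges)
            bf_core = brute_core_numbers(nodes, edges)
            for n in nodes:
                assert btw[n] == pytest.approx(bf_btw[n], abs=1e-9)
                assert clo[n] == pytest.approx(bf_clo[n], abs=1e-9)
                assert core[n] == bf_core[n]

    def test_networkx_agreement_larger_graphs(self):
        rng = np.random.default_rng(99)
        for _ in range(10):
            g = nx.gnp_random_graph(30, 0.15, seed=int(rng.integers(2**31)))
            net = InteractionNetwork.from_networkx(g)
            nx_btw = nx.betweenness_centrality(g, normalized=False)
            nx_core = nx.core_number(g)
            btw = betweenness_map(net)
            clo = closeness_map(net)
            core = core_number_map(net)
            for n in g.nodes:
                assert btw[str(n)] == pytest.approx(nx_btw[n], abs=1e-9)
                total = sum(nx.shortest_path_length(g, n).values())
                assert clo[str(n)] == pytest.approx(1 / total if total else 0.0)
                assert core[str(n)] == nx_core[n]

    def test_betweenness_sum_matches_interior_vertex_total(self):
        """Sum of betweenness equals the summed interior-vertex expectation
        over connected pairs, cross-checked against brute force."""
        rng = np.random.default_rng(7)
        for _ in range(20):
            nodes, edges = random_net(rng)
            total = sum(betweenness_map(build(nodes, edges)).values())
            bf_total = sum(brute_betweenness(nodes, edges).values())
            assert total == pytest.approx(bf_total, abs=1e-9)
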