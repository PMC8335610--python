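"""Follow-graph operators: propagation, communities, k-core, summaries."""

import itertools

import networkx as nx
import numpy as np
import pytest

from anstages.network import (
    CommunityPartition, build_graph, detect_communities, graph_summary,
    k_core_filter, map_communities_to_groups, pagerank_scores,
    propagate_validation_groups,
)


class TestBuildGraph:
    def test_followee_cap(self):
        edges = [("u", f"t{i}") for i in range(150)]
        g = build_graph(edges, followee_cap_per_user=100, seed=1)
        assert g.out_degree("u") == 100

    def test_duplicates_and_self_loops_dropped(self):
        g = build_graph([("a", "b"), ("a", "b"), ("a", "a")])
        assert list(g.edges) == [("a", "b")]

    def test_deterministic_under_seed(self):
        edges = [("u", f"t{i}") for i in range(150)]
        a = build_graph(edges, 50, seed=9)
        b = build_graph(edges, 50, seed=9)
        assert set(a.edges) == set(b.edges)


def propagation_oracle(graph, seeds):
    """Independent two-pass strict-plurality majority propagation."""
    assign = {n: (g, 1) for n, g in seeds.items() if n in graph}
    current = dict(seeds)
    for level in (2, 3):
        new = {}
        for node in graph.nodes:
            if node in assign:
                continue
            counts = {}
            for pred in graph.predecessors(node):
                if pred in current and assign.get(pred, (None, 0))[1] == level - 1:
                    g = current[pred]
                    counts[g] = counts.get(g, 0) + 1
            if counts:
                best = max(counts.values())
                winners = [g for g, c in counts.items() if c == best]
                if len(winners) == 1:
                    new[node] = winners[0]
        for n, g in new.items():
            assign[n] = (g, level)
        current = new
    return assign


class TestPropagation:
    def test_node_followed_only_by_an_seeds(self):
        g = nx.DiGraph([("s1", "x"), ("s2", "x")])
        res = propagate_validation_groups(g, {"s1": "AN", "s2": "AN"})
        assert res.assignment["x"] == ("AN", 2)

    def test_tie_leaves_unassigned(self):
        g = nx.DiGraph([("s1", "x"), ("s2", "x")])
        res = propagate_validation_groups(g, {"s1": "AN", "s2": "focused_control"})
        assert "x" not in res.assignment

    def test_level3_uses_only_level2(self):
        # chain: seed -> a -> b ; b's only labeled follower is a (level 2)
        g = nx.DiGraph([("s", "a"), ("a", "b"), ("s2", "b")])
        res = propagate_validation_groups(g, {"s": "AN"})
        # s2 is unlabeled and never assigned, so b sees only a at level 3
        assert res.assignment["a"] == ("AN", 2)
        assert res.assignment["b"] == ("AN", 3)

    def test_seed_labels_never_overwritten(self):
        g = nx.DiGraph([("s1", "s2")])
        res = propagate_validation_groups(g, {"s1": "AN", "s2": "recovered"})
        assert res.assignment["s2"] == ("recovered", 1)

    def test_empty_seed_error(self):
        with pytest.raises(ValueError):
            propagate_validation_groups(nx.DiGraph([("a", "b")]), {})

    def test_matches_two_pass_oracle_on_random_graphs(self, rng):
        for trial in range(10):
            g = nx.gnp_random_graph(30, 0.12, directed=True,
                                    seed=int(rng.integers(1 << 30)))
            seeds = {n: ("AN" if n % 2 else "focused_control")
                     for n in range(6)}
            res = propagate_validation_groups(g, seeds)
            assert res.assignment == propagation_oracle(g, seeds)


def modularity_oracle(und, communities):
    """Direct evaluation of the modularity formula on an undirected graph."""
    m = und.number_of_edges()
    deg = dict(und.degree())
    q = 0.0
    for c in communities:
        nodes = list(c)
        lc = sum(1 for u, v in itertools.combinations(nodes, 2) if und.has_edge(u, v))
        lc += sum(1 for u in nodes if und.has_edge(u, u))
        dc = sum(deg[u] for u in nodes)
        q += lc / m - (dc / (2 * m)) ** 2
    return q


class TestCommunities:
    def _two_cliques(self):
        g = nx.DiGraph()
        for a, b in itertools.combinations(range(5), 2):
            g.add_edge(f"x{a}", f"x{b}")
            g.add_edge(f"y{a}", f"y{b}")
        g.add_edge("x0", "y0")
        return g

    def test_two_cliques_two_communities(self):
        part = detect_communities(self._two_cliques(), seed=0)
        comms = part.communities()
        assert len(comms) == 2
        sides = [{n[0] for n in c} for c in comms.values()]
        assert {"x"} in sides and {"y"} in sides

    def test_single_node(self):
        g = nx.DiGraph()
        g.add_node("a")
        part = detect_communities(g)
        assert part.modularity == 0.0 and part.membership == {"a": 0}

    def test_modularity_matches_formula_oracle(self, rng):
        g = nx.gnp_random_graph(20, 0.25, seed=4, directed=True)
        part = detect_communities(g, seed=2)
        und = nx.Graph(g)
        comms = list(part.communities().values())
        assert part.modularity == pytest.approx(modularity_oracle(und, comms),
                                                abs=1e-12)

    def test_deterministic_under_seed(self):
        g = nx.gnp_random_graph(40, 0.1, seed=8, directed=True)
        a = detect_communities(g, seed=5).membership
        b = detect_communities(g, seed=5).membership
        assert a == b


class TestCommunityMapping:
    def test_dominant_group(self):
        part = CommunityPartition({f"n{i}": 0 for i in range(6)}, 0.0)
        labels = {f"n{i}": "AN" for i in range(5)}
        labels["n5"] = "focused_control"
        m = map_communities_to_groups(part, labels)
        assert m[0]["dominant"] == ["AN"]

    def test_tie_reports_both(self):
        part = CommunityPartition({"a": 0, "b": 0, "c": 0, "d": 0}, 0.0)
        labels = {"a": "AN", "b": "AN", "c": "recovered", "d": "recovered"}
        assert map_communities_to_groups(part, labels)[0]["dominant"] == \
            ["AN", "recovered"]

    def test_unlabeled_community_undefined(self):
        part = CommunityPartition({"a": 0, "b": 1}, 0.0)
        m = map_communities_to_groups(part, {"a": "AN"})
        assert m[1]["dominant"] == ["undefined"]

    def test_ratios_sum_to_one(self, rng):
        nodes = [f"n{i}" for i in range(60)]
        part = CommunityPartition(
            {n: int(rng.integers(4)) for n in nodes}, 0.0)
        labels = {n: ["AN", "recovered", "treatment"][int(rng.integers(3))]
                  for n in nodes[:40]}
        for info in map_communities_to_groups(part, labels).values():
            if info["ratios"]:
                assert sum(info["ratios"].values()) == pytest.approx(1.0)


class TestSummary:
    def test_directed_three_cycle(self):
        g = nx.DiGraph([("a", "b"), ("b", "c"), ("c", "a")])
        s = graph_summary(g)
        assert s["average_degree"] == 1.0
        assert s["diameter"] == 1.0
        assert s["average_clustering"] == 1.0

    def test_path_graph_diameter(self):
        g = nx.DiGraph([("a", "b"), ("b", "c"), ("c", "d")])
        assert graph_summary(g)["diameter"] == 3.0

    def test_bfs_oracle_on_random_graph(self, rng):
        g = nx.gnp_random_graph(50, 0.08, seed=3, directed=True)
        und = nx.Graph(g)
        wcc = max(nx.connected_components(und), key=len)
        sub = und.subgraph(wcc)
        dists = [d for n in sub
                 for d in nx.single_source_shortest_path_length(sub, n).values()
                 if d > 0]
        s = graph_summary(g)
        assert s["diameter"] == max(dists)
        assert s["average_path_length"] == pytest.approx(np.mean(dists))


def kcore_oracle(und, k):
    g = nx.Graph(und)
    g.remove_edges_from(nx.selfloop_edges(g))
    while True:
        drop = [n for n, d in g.degree() if d < k]
        if not drop:
            return g
        g.remove_nodes_from(drop)


class TestKCore:
    def test_tree_empties_at_k2(self):
        g = nx.balanced_tree(2, 3)
        assert k_core_filter(g, 2).number_of_nodes() == 0

    def test_triangle_unchanged(self):
        g = nx.cycle_graph(3)
        assert set(k_core_filter(g, 2).nodes) == {0, 1, 2}

    def test_matches_iterative_deletion_oracle(self, rng):
        for trial in range(10):
            g = nx.gnp_random_graph(40, 0.08, seed=int(rng.integers(1 << 30)))
            for k in (1, 2, 3):
                ours = k_core_filter(g, k)
                oracle = kcore_oracle(g, k)
                assert set(ours.nodes) == set(oracle.nodes)
                assert set(map(frozenset, ours.edges)) == \
                    set(map(frozenset, oracle.edges))

    def test_idempotent_and_monotone(self):
        g = nx.gnp_random_graph(40, 0.15, seed=2)
        c2 = k_core_filter(g, 2)
        assert set(k_core_filter(c2, 2).nodes) == set(c2.nodes)
        c3 = k_core_filter(g, 3)
        assert set(c3.nodes) <= set(c2.nodes)


class TestPageRank:
    def test_symmetric_two_cycle(self):
        g = nx.DiGraph([("a", "b"), ("b", "a")])
        pr = pagerank_scores(g)
        assert pr["a"] == pytest.approx(0.5) and pr["b"] == pytest.approx(0.5)

    def test_scores_sum_to_one_with_dangling(self):
        g = nx.DiGraph([("a", "b"), ("c", "b")])  # b dangles
        assert sum(pagerank_scores(g).values()) == pytest.approx(1.0, abs=1e-9)
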