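"""Follow-graph analysis: validation-group propagation, community
detection, k-core filtering and summary statistics.

The graph is directed (follower -> followee).  Validation groups extend the
manually labeled seed groups by followee-majority: an unlabeled node is
assigned to the group holding a strict plurality among its already-assigned
in-neighbors (its followers), first using only seed (level-1) labels
(giving level 2), then once more using level-2 labels (giving level 3).
Ties leave a node unassigned.  Community detection (Louvain), k-core and
the distance summaries operate on the undirected projection; disconnected
graphs report distances on the largest weakly connected component.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

from .synth import substream

log = logging.getLogger(__name__)


def build_graph(edges: Iterable[tuple[str, str]],
                followee_cap_per_user: int = 100,
                seed: int = 0) -> nx.DiGraph:
    """Directed follow graph; at most ``followee_cap_per_user`` out-edges
    are retained per user (seeded random sample), self-loops and duplicate
    edges dropped."""
    by_src: dict[str, list[str]] = {}
    nodes: set[str] = set()
    for src, dst in edges:
        nodes.add(src)
        nodes.add(dst)
        if src == dst:
            continue
        lst = by_src.setdefault(src, [])
        if dst not in lst:
            lst.append(dst)
    g = nx.DiGraph()
    g.add_nodes_from(sorted(nodes))
    for src in sorted(by_src):
        targets = by_src[src]
        if len(targets) > followee_cap_per_user:
            rng = substream(seed, "followee_cap", src)
            idx = rng.choice(len(targets), size=followee_cap_per_user, replace=False)
            targets = [targets[i] for i in sorted(idx)]
        g.add_edges_from((src, t) for t in targets)
    return g


@dataclass
class ValidationAssignment:
    assignment: dict[str, tuple[str, int]] = field(default_factory=dict)

    def group_of(self, node: str) -> str | None:
        entry = self.assignment.get(node)
        return entry[0] if entry else None

    def by_level(self, level: int) -> dict[str, str]:
        return {n: g for n, (g, lv) in self.assignment.items() if lv == level}


def _plurality(counts: Mapping[str, int]) -> str | None:
    if not counts:
        return None
    best = max(counts.values())
    winners = [g for g, c in counts.items() if c == best]
    return winners[0] if len(winners) == 1 else None


def propagate_validation_groups(graph: nx.DiGraph,
                                seed_labels: Mapping[str, str],
                                max_level: int = 3) -> ValidationAssignment:
    """Followee-majority propagation of seed labels.

    Level 1 is the seed labels themselves.  Each later level assigns an
    unlabeled node to the strict-plurality group among its in-neighbors
    holding exactly the previous level's assignment (synchronous update);
    plurality ties leave the node unassigned.  A node keeps the earliest
    level at which it becomes assignable.
    """
    if not seed_labels:
        raise ValueError("seed_labels: empty seed set")
    assign: dict[str, tuple[str, int]] = {
        n: (g, 1) for n, g in seed_labels.items() if n in graph
    }
    prev_level = {n: g for n, (g, _) in assign.items()}
    for level in range(2, max_level + 1):
        new: dict[str, str] = {}
        for node in graph.nodes:
            if node in assign:
                continue
            counts: dict[str, int] = {}
            for follower in graph.predecessors(node):
                g = prev_level.get(follower)
                if g is not None:
                    counts[g] = counts.get(g, 0) + 1
            winner = _plurality(counts)
            if winner is not None:
                new[node] = winner
        for node, g in new.items():
            assign[node] = (g, level)
        prev_level = new
    return ValidationAssignment(assign)


@dataclass
class CommunityPartition:
    membership: dict[str, int]
    modularity: float

    def communities(self) -> dict[int, set[str]]:
        out: dict[int, set[str]] = {}
        for n, c in self.membership.items():
            out.setdefault(c, set()).add(n)
        return out


def detect_communities(graph: nx.DiGraph | nx.Graph, resolution: float = 1.0,
                       seed: int = 0) -> CommunityPartition:
    """Louvain communities on the undirected projection, with the
    modularity of the returned partition."""
    if graph.number_of_nodes() == 0:
        raise ValueError("graph: empty")
    und = nx.Graph(graph)
    comms = nx.community.louvain_communities(und, resolution=resolution, seed=seed)
    membership = {n: i for i, c in enumerate(comms) for n in c}
    mod = nx.community.modularity(und, comms, resolution=resolution) if und.number_of_edges() else 0.0
    return CommunityPartition(membership, float(mod))


def map_communities_to_groups(partition: CommunityPartition,
                              labels: Mapping[str, str]) -> dict[int, dict]:
    """Per community: labeled-member counts per group, composition ratios
    (summing to 1 over labeled members) and the dominant group(s) — a count
    tie reports all tied groups."""
    if not labels:
        raise ValueError("labels: need at least one labeled node")
    out: dict[int, dict] = {}
    for cid, members in partition.communities().items():
        counts: dict[str, int] = {}
        for n in members:
            g = labels.get(n)
            if g is not None:
                counts[g] = counts.get(g, 0) + 1
        total = sum(counts.values())
        if total == 0:
            out[cid] = {"counts": {}, "ratios": {}, "dominant": ["undefined"],
                        "size": len(members)}
            continue
        best = max(counts.values())
        out[cid] = {
            "counts": counts,
            "ratios": {g: c / total for g, c in counts.items()},
            "dominant": sorted(g for g, c in counts.items() if c == best),
            "size": len(members),
        }
    return out


def graph_summary(graph: nx.DiGraph) -> dict[str, float]:
    """Node/edge counts, average degree (directed edges per node), and
    diameter / average path length / average clustering on the undirected
    projection of the largest weakly connected component."""
    if graph.number_of_nodes() == 0:
        raise ValueError("graph: empty")
    n, m = graph.number_of_nodes(), graph.number_of_edges()
    wcc = max(nx.weakly_connected_components(graph), key=len)
    if len(wcc) < n:
        log.info("graph_summary: distances on largest WCC (%d of %d nodes)",
                 len(wcc), n)
    und = nx.Graph(graph.subgraph(wcc))
    if und.number_of_nodes() > 1:
        diameter = float(nx.diameter(und))
        apl = float(nx.average_shortest_path_length(und))
    else:
        diameter, apl = 0.0, 0.0
    clustering = float(nx.average_clustering(nx.Graph(graph)))
    return {"node_count": float(n), "edge_count": float(m),
            "average_degree": m / n, "diameter": diameter,
            "average_path_length": apl, "average_clustering": clustering}


def k_core_filter(graph: nx.DiGraph | nx.Graph, k: int = 2) -> nx.Graph:
    """Maximal subgraph of the undirected projection in which every node
    has degree >= k (iterative peeling to the fixpoint)."""
    if k < 0:
        raise ValueError("k: must be >= 0")
    und = nx.Graph(graph)
    und.remove_edges_from(nx.selfloop_edges(und))
    return nx.k_core(und, k)


def pagerank_scores(graph: nx.DiGraph, damping: float = 0.85) -> dict[str, float]:
    """Damped PageRank; dangling mass redistributed uniformly; scores sum
    to 1."""
    if graph.number_of_nodes() == 0:
        raise ValueError("graph: empty")
    return nx.pagerank(graph, alpha=damping)


def assigned_region_cross_edges(graph: nx.DiGraph,
                                assignment: ValidationAssignment,
                                group_a: str, group_b: str) -> dict[str, float]:
    """Edge mix between two groups' assigned regions: counts of edges
    within each region and across them, and the cross fraction — the
    polarization summary for the AN vs focused-control comparison."""
    region = {n: g for n, (g, _) in assignment.assignment.items()
              if g in (group_a, group_b)}
    within_a = within_b = cross = 0
    for u, v in graph.edges:
        gu, gv = region.get(u), region.get(v)
        if gu is None or gv is None:
            continue
        if gu == gv == group_a:
            within_a += 1
        elif gu == gv == group_b:
            within_b += 1
        else:
            cross += 1
    total = within_a + within_b + cross
    return {"within_a": within_a, "within_b": within_b, "cross": cross,
            "cross_fraction": cross / total if total else float("nan")}
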