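"""Shared fixtures: small reference graphs and independent oracles."""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np
import pytest

from ppimodules.netio import InteractionNetwork


def net_from_nx(g: nx.Graph, label: str = "LIT") -> InteractionNetwork:
    relabeled = nx.relabel_nodes(g, {n: f"n{n:02d}" for n in g.nodes})
    return InteractionNetwork(class_label=label, graph=relabeled)


def brute_force_cpm(g: nx.Graph, k: int) -> set[frozenset]:
    """Independent clique-percolation oracle.

    Enumerates every k-clique directly, links cliques sharing k-1 nodes, and
    returns the node union of each connected clique group.
    """
    cliques = [
        frozenset(c)
        for c in itertools.combinations(sorted(g.nodes), k)
        if all(g.has_edge(a, b) for a, b in itertools.combinations(c, 2))
    ]
    parent = list(range(len(cliques)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, j in itertools.combinations(range(len(cliques)), 2):
        if len(cliques[i] & cliques[j]) == k - 1:
            parent[find(i)] = find(j)
    groups: dict[int, set] = {}
    for i, c in enumerate(cliques):
        groups.setdefault(find(i), set()).update(c)
    return {frozenset(v) for v in groups.values()}


def all_partitions(items: list):
    """Every set partition of ``items`` (restricted-growth enumeration)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for sub in all_partitions(rest):
        for i in range(len(sub)):
            yield sub[:i] + [[first] + sub[i]] + sub[i + 1 :]
        yield [[first]] + sub


def best_partition_q(net: InteractionNetwork) -> float:
    """Exhaustive-search maximum modularity over all partitions."""
    from ppimodules.detect import modularity_q

    nodes = sorted(net.nodes)
    assert len(nodes) <= 8, "exhaustive search is for small graphs only"
    return max(
        modularity_q(net, [set(b) for b in part]).q_value
        for part in all_partitions(nodes)
    )


@pytest.fixture
def two_cliques_bridge() -> InteractionNetwork:
    """Two K4s joined by a single bridge edge."""
    g = nx.disjoint_union(nx.complete_graph(4), nx.complete_graph(4))
    g.add_edge(3, 4)
    return net_from_nx(g)


@pytest.fixture
def four_triangles() -> InteractionNetwork:
    return net_from_nx(nx.disjoint_union_all([nx.complete_graph(3)] * 4))


@pytest.fixture
def random_graph_corpus() -> list[nx.Graph]:
    """Seeded corpus of small connected graphs for oracle comparisons."""
    rng = np.random.default_rng(20260927)
    corpus = []
    for n in range(4, 11):
        for p in (0.3, 0.5, 0.7):
            for _ in range(3):
                g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
                if nx.is_connected(g) and g.number_of_edges() > 0:
                    corpus.append(g)
    assert len(corpus) >= 30
    return corpus
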