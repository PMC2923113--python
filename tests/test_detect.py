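"""Detectors: clique percolation, MCODE cores, modularity maximization,
walktrap, community selection and the size census."""

from __future__ import annotations

import networkx as nx
import numpy as np
import pytest

from conftest import best_partition_q, brute_force_cpm, net_from_nx
from ppimodules.detect import (
    DetectionParams,
    detect_cpm,
    detect_greedy,
    detect_mcode,
    detect_walktrap,
    modularity_q,
    select_cfinder_communities,
    size_histogram,
)
from ppimodules.netio import InteractionNetwork, Module


class TestCpm:
    def test_single_clique(self):
        net = net_from_nx(nx.complete_graph(4))
        mods = detect_cpm(net, 3)
        assert len(mods) == 1
        assert mods[0].members == frozenset(net.nodes)
        assert mods[0].k_param == 3
        assert mods[0].rank_score == 4

    def test_two_k4_sharing_two_nodes_stay_separate_at_k4(self):
        # shared overlap of 2 < k-1 = 3, so two communities overlapping in 2
        g = nx.complete_graph(4)
        g.add_edges_from(
            (a, b)
            for a in (2, 3, 4, 5)
            for b in (2, 3, 4, 5)
            if a < b
        )
        net = net_from_nx(g)
        mods = detect_cpm(net, 4)
        assert len(mods) == 2
        members = [m.members for m in mods]
        assert len(members[0] & members[1]) == 2
        assert {len(m) for m in members} == {4}

    def test_triangle_free_graph_yields_nothing(self):
        net = net_from_nx(nx.cycle_graph(6))
        assert detect_cpm(net, 3) == []

    def test_k_below_three_rejected(self):
        net = net_from_nx(nx.complete_graph(3))
        with pytest.raises(ValueError):
            detect_cpm(net, 2)

    def test_matches_brute_force_oracle_on_corpus(self, random_graph_corpus):
        for g in random_graph_corpus:
            net = net_from_nx(g)
            for k in (3, 4, 5):
                expected = brute_force_cpm(net.graph, k)
                got = {m.members for m in detect_cpm(net, k)}
                assert got == expected, f"n={g.number_of_nodes()}, k={k}"

    def test_nested_resolution(self, random_graph_corpus):
        # every k community lies inside some k-1 community
        for g in random_graph_corpus[:12]:
            net = net_from_nx(g)
            coarse = [m.members for m in detect_cpm(net, 3)]
            for k in (4, 5):
                for mod in detect_cpm(net, k):
                    assert any(mod.members <= c for c in coarse)
                coarse = [m.members for m in detect_cpm(net, k)]

    def test_planted_clique_recovery(self):
        from ppimodules.synthetic_data import PlantSpec, generate_interactome_classes

        spec = PlantSpec(
            n_plants=8,
            plant_size_range=(6, 6),
            intra_density=1.0,
            background_nodes=200,
            background_density=0.01,
            seed=42,
        )
        truth, _ = generate_interactome_classes(spec)
        mods = detect_cpm(truth.true_network, 4)
        found = {m.members for m in mods}
        for plant in truth.plants.values():
            assert frozenset(plant) in found


class TestMcode:
    def test_k5_single_module(self):
        net = net_from_nx(nx.complete_graph(5))
        mods = detect_mcode(net)
        assert len(mods) == 1
        assert mods[0].members == frozenset(net.nodes)
        assert mods[0].rank_score == pytest.approx(2.0)
        assert mods[0].k_param == 4

    def test_haircut_removes_pendant(self):
        g = nx.complete_graph(4)
        g.add_edge(3, 4)  # pendant node
        net = net_from_nx(g)
        mods = detect_mcode(net)
        assert len(mods) == 1
        assert len(mods[0].members) == 4
        assert mods[0].rank_score == pytest.approx(1.5)

    def test_star_graph_yields_nothing(self):
        net = net_from_nx(nx.star_graph(5))
        assert detect_mcode(net) == []

    def test_haircut_postcondition_on_random_graphs(self, random_graph_corpus):
        for g in random_graph_corpus:
            net = net_from_nx(g)
            for mod in detect_mcode(net):
                sub = net.graph.subgraph(mod.members)
                assert min(dict(sub.degree).values()) >= 2
                # declared coreness is the actual minimum intra-module degree
                assert mod.k_param == min(dict(sub.degree).values())

    def test_modules_are_disjoint_without_fluff(self, random_graph_corpus):
        for g in random_graph_corpus[:10]:
            mods = detect_mcode(net_from_nx(g))
            seen: set = set()
            for m in mods:
                assert not (m.members & seen)
                seen |= m.members


class TestModularity:
    def test_single_module_is_zero(self, two_cliques_bridge):
        s = modularity_q(two_cliques_bridge, [two_cliques_bridge.nodes])
        assert s.q_value == pytest.approx(0.0, abs=1e-12)
        assert s.trace == pytest.approx(1.0)

    def test_two_disjoint_triangles(self):
        g = nx.disjoint_union(nx.complete_graph(3), nx.complete_graph(3))
        net = net_from_nx(g)
        blocks = [{"n00", "n01", "n02"}, {"n03", "n04", "n05"}]
        assert modularity_q(net, blocks).q_value == pytest.approx(0.5)

    def test_path_split(self):
        net = InteractionNetwork.from_edges(
            [("a", "b"), ("b", "c"), ("c", "d")], "LIT"
        )
        s = modularity_q(net, [{"a", "b"}, {"c", "d"}])
        assert s.q_value == pytest.approx(1 / 6)

    def test_mixing_fractions_sum_to_one(self, random_graph_corpus):
        rng = np.random.default_rng(3)
        for g in random_graph_corpus[:10]:
            net = net_from_nx(g)
            nodes = sorted(net.nodes)
            labels = rng.integers(0, 3, size=len(nodes))
            blocks = [
                {n for n, l in zip(nodes, labels) if l == i} for i in range(3)
            ]
            blocks = [b for b in blocks if b]
            s = modularity_q(net, blocks)
            assert sum(s.mixing_fraction.values()) == pytest.approx(1.0, abs=1e-12)
            assert s.q_value < 1.0
            assert all(0.0 <= v <= 1.0 for v in s.module_link_share.values())

    def test_agrees_with_networkx(self, random_graph_corpus):
        rng = np.random.default_rng(11)
        for g in random_graph_corpus[:10]:
            net = net_from_nx(g)
            nodes = sorted(net.nodes)
            labels = rng.integers(0, 2, size=len(nodes))
            blocks = [
                {n for n, l in zip(nodes, labels) if l == i} for i in range(2)
            ]
            blocks = [b for b in blocks if b]
            expected = nx.community.modularity(net.graph, blocks)
            assert modularity_q(net, blocks).q_value == pytest.approx(expected)

    def test_errors(self):
        net = InteractionNetwork.from_edges([("a", "b")], "LIT")
        with pytest.raises(ValueError):
            modularity_q(net, [{"a"}])  # b missing
        empty = InteractionNetwork.from_edges([], "LIT", nodes=["a"])
        with pytest.raises(ValueError):
            modularity_q(empty, [{"a"}])


# Curated small modular graphs (clique blocks with sparse bridges) where the
# agglomerative merge paths provably reach the global Q optimum.
def _optimum_corpus() -> list[nx.Graph]:
    g1 = nx.barbell_graph(4, 0)  # two K4s joined by one bridge
    g2 = nx.complete_graph(5)
    g3 = nx.disjoint_union(nx.complete_graph(3), nx.complete_graph(3))
    g4 = nx.disjoint_union_all([nx.complete_graph(3)] * 2)
    g4.add_edge(2, 3)
    g5 = nx.complete_graph(4)  # K4 with a pendant triangle
    g5.add_edges_from([(3, 4), (4, 5), (5, 6), (4, 6)])
    g6 = nx.disjoint_union_all(
        [nx.complete_graph(3), nx.complete_graph(3), nx.complete_graph(2)]
    )
    return [g1, g2, g3, g4, g5, g6]


class TestGreedy:
    def test_two_cliques_bridge(self, two_cliques_bridge):
        mods, summary = detect_greedy(two_cliques_bridge)
        assert {frozenset(m.members) for m in mods} == {
            frozenset({"n00", "n01", "n02", "n03"}),
            frozenset({"n04", "n05", "n06", "n07"}),
        }
        assert summary.q_value == pytest.approx(
            best_partition_q(two_cliques_bridge)
        )

    def test_single_clique_one_module(self):
        net = net_from_nx(nx.complete_graph(5))
        mods, summary = detect_greedy(net)
        assert len(mods) == 1
        assert summary.q_value == pytest.approx(0.0, abs=1e-12)

    def test_four_triangles(self, four_triangles):
        mods, summary = detect_greedy(four_triangles)
        assert len(mods) == 4
        assert summary.q_value == pytest.approx(0.75)

    def test_reaches_exhaustive_optimum(self):
        for g in _optimum_corpus():
            net = net_from_nx(g)
            _, summary = detect_greedy(net)
            assert summary.q_value == pytest.approx(best_partition_q(net))

    def test_self_consistency(self, random_graph_corpus):
        for g in random_graph_corpus[:10]:
            net = net_from_nx(g)
            mods, summary = detect_greedy(net)
            singles = net.nodes - set().union(*[m.members for m in mods]) if mods else net.nodes
            blocks = [set(m.members) for m in mods] + [{n} for n in singles]
            assert modularity_q(net, blocks).q_value == pytest.approx(
                summary.q_value
            )

    def test_edgeless_errors(self):
        net = InteractionNetwork.from_edges([], "LIT", nodes=["a", "b"])
        with pytest.raises(ValueError):
            detect_greedy(net)


class TestWalktrap:
    def test_two_cliques_bridge(self, two_cliques_bridge):
        mods, summary = detect_walktrap(two_cliques_bridge, 4)
        assert {frozenset(m.members) for m in mods} == {
            frozenset({"n00", "n01", "n02", "n03"}),
            frozenset({"n04", "n05", "n06", "n07"}),
        }

    def test_complete_graph_one_module(self):
        net = net_from_nx(nx.complete_graph(6))
        mods, summary = detect_walktrap(net, 4)
        assert len(mods) == 1
        assert summary.q_value == pytest.approx(0.0, abs=1e-12)

    def test_two_disjoint_triangles(self):
        g = nx.disjoint_union(nx.complete_graph(3), nx.complete_graph(3))
        mods, summary = detect_walktrap(net_from_nx(g), 4)
        assert len(mods) == 2
        assert summary.q_value == pytest.approx(0.5)

    def test_reaches_exhaustive_optimum(self):
        for g in _optimum_corpus():
            net = net_from_nx(g)
            _, summary = detect_walktrap(net, 4)
            assert summary.q_value == pytest.approx(best_partition_q(net))

    def test_self_consistency(self, random_graph_corpus):
        for g in random_graph_corpus[:10]:
            net = net_from_nx(g)
            mods, summary = detect_walktrap(net, 4)
            singles = net.nodes - set().union(*[m.members for m in mods]) if mods else net.nodes
            blocks = [set(m.members) for m in mods] + [{n} for n in singles]
            assert modularity_q(net, blocks).q_value == pytest.approx(
                summary.q_value
            )

    def test_agrees_with_igraph_on_separable_graph(self):
        igraph = pytest.importorskip("igraph")
        g = nx.disjoint_union(nx.complete_graph(5), nx.complete_graph(5))
        g.add_edge(4, 5)
        net = net_from_nx(g)
        mods, _ = detect_walktrap(net, 4)
        ig = igraph.Graph(edges=list(g.edges), n=10)
        ref = ig.community_walktrap(steps=4).as_clustering()
        ref_sets = {frozenset(f"n{v:02d}" for v in c) for c in ref}
        assert {m.members for m in mods} == ref_sets


class TestSelection:
    def _mod(self, mid, size, k):
        return Module(mid, frozenset(f"p{mid}{i}" for i in range(size)), "CPM", k, size)

    def test_backward_exclusivity(self):
        shared = frozenset({"a", "b", "c", "d", "e"})
        m5 = Module("Int-1", shared, "CPM", 5, 5)
        m4 = Module("Int-2", shared, "CPM", 4, 5)
        selected = select_cfinder_communities({5: [m5], 4: [m4]})
        assert selected == [m5]

    def test_oversize_dropped(self):
        big = Module("Int-1", frozenset(f"p{i}" for i in range(250)), "CPM", 4, 250)
        assert select_cfinder_communities({4: [big]}) == []

    def test_forward_keeps_five_nearest_median(self):
        sizes = [4, 5, 6, 7, 8, 20, 40]
        mods = [self._mod(f"Int-{i+1}", s, 4) for i, s in enumerate(sizes)]
        selected = select_cfinder_communities({4: mods})
        # median size 7; the five nearest are sizes 4..8
        assert sorted(m.size for m in selected) == [4, 5, 6, 7, 8]

    def test_small_k_excluded(self):
        mods = [self._mod("Int-1", 5, 3)]
        assert select_cfinder_communities({3: mods}) == []

    def test_ordering_by_k_then_size(self):
        m_a = self._mod("Int-1", 6, 5)
        m_b = self._mod("Int-2", 8, 4)
        m_c = self._mod("Int-3", 4, 4)
        selected = select_cfinder_communities({5: [m_a], 4: [m_b, m_c]})
        assert [m.module_id for m in selected] == ["Int-1", "Int-2", "Int-3"]


class TestSizeHistogram:
    def test_census(self):
        mods = [
            Module("Int-1", frozenset("abc"), "CPM", 3, 3),
            Module("Int-2", frozenset("xyz"), "CPM", 3, 3),
            Module("Int-3", frozenset("vwxyz"), "CPM", 3, 5),
        ]
        assert size_histogram(mods) == {3: 2, 5: 1}

    def test_empty(self):
        assert size_histogram([]) == {}

    def test_conservation(self, random_graph_corpus):
        net = net_from_nx(random_graph_corpus[0])
        mods = detect_cpm(net, 3)
        assert sum(size_histogram(mods).values()) == len(mods)
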