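"""Module-extraction algorithms for protein interactomes.

Four detectors are provided:

* :func:`detect_cpm` — clique percolation (overlapping k-clique communities),
* :func:`detect_mcode` — vertex-weighted core mining with haircut/fluff
  post-processing (Molecular Complex Detection),
* :func:`detect_greedy` — agglomerative Newman modularity maximization,
* :func:`detect_walktrap` — random-walk-distance agglomeration.

Modularity Q of a disjoint partition follows the Newman–Girvan convention:
with m edges, l_i intra-module edges and d_i total degree of module i,

    Q = sum_i [ l_i / m  -  (d_i / 2m)^2 ].

All detectors iterate nodes in sorted order and break ties deterministically,
so module ids are reproducible run to run.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from statistics import median
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
import numpy as np

from .netio import (
    CPM,
    MAXMOD,
    MCODE,
    WALKTRAP,
    InteractionNetwork,
    Module,
    assign_module_ids,
)

_TOL = 1e-12


@dataclass(frozen=True)
class PartitionSummary:
    """Edge-mixing bookkeeping for a disjoint partition of a network.

    ``mixing_fraction[(i, j)]`` is the fraction of edge mass linking module i
    to module j (e_ij); diagonal entries are intra-module edge fractions.
    ``module_link_share[i]`` is E_i = sum_j e_ij = d_i / 2m.  Q equals
    Tr[E] - sum_i E_i^2; it is 0 for the single-module partition and < 1.
    """

    module_count: int
    mixing_fraction: Mapping[tuple[int, int], float]
    module_link_share: Mapping[int, float]
    trace: float
    q_value: float


@dataclass(frozen=True)
class DetectionParams:
    """Tunable parameters shared by the detectors and community selection."""

    k_min: int = 3
    k_max: Optional[int] = None
    mcode_node_score_cutoff: float = 0.2
    mcode_haircut: bool = True
    mcode_fluff: bool = False
    mcode_fluff_density: float = 0.1
    mcode_max_depth: int = 100
    walktrap_steps: int = 4
    max_community_size: int = 200
    representative_subset_size: int = 5

    def __post_init__(self) -> None:
        if self.k_min < 2:
            raise ValueError("k_min must be >= 2")
        if self.mcode_max_depth < 1:
            raise ValueError("mcode_max_depth must be >= 1")
        if self.walktrap_steps < 1:
            raise ValueError("walktrap_steps must be >= 1")
        if not 0.0 <= self.mcode_node_score_cutoff <= 1.0:
            raise ValueError("mcode_node_score_cutoff must be in [0, 1]")


# ---------------------------------------------------------------------------
# Modularity


def modularity_q(
    network: InteractionNetwork, partition: Sequence[Iterable[str]]
) -> PartitionSummary:
    """Evaluate modularity Q and the full mixing matrix for a partition.

    The partition must cover every node exactly once; the network must have
    at least one edge.
    """
    g = network.graph
    m = g.number_of_edges()
    if m == 0:
        raise ValueError("modularity is undefined for an edgeless network")
    blocks = [set(b) for b in partition]
    assignment: dict[str, int] = {}
    for i, block in enumerate(blocks):
        for node in block:
            if node in assignment:
                raise ValueError(f"node {node!r} appears in more than one module")
            if node not in g:
                raise ValueError(f"node {node!r} is not in the network")
            assignment[node] = i
    missing = set(g.nodes) - set(assignment)
    if missing:
        raise ValueError(f"partition does not cover nodes: {sorted(missing)[:5]}")

    n_blocks = len(blocks)
    # accumulate integer edge counts; divide once so exact limits (Q = 0 for
    # the single-module partition) hold without floating-point drift
    counts: dict[tuple[int, int], int] = {}
    for a, b in g.edges:
        i, j = assignment[a], assignment[b]
        if i == j:
            counts[(i, i)] = counts.get((i, i), 0) + 2
        else:
            counts[(i, j)] = counts.get((i, j), 0) + 1
            counts[(j, i)] = counts.get((j, i), 0) + 1
    e = {key: c / (2 * m) for key, c in counts.items()}
    degree_mass = {i: 0 for i in range(n_blocks)}
    for (i, _j), c in counts.items():
        degree_mass[i] += c
    share = {i: dm / (2 * m) for i, dm in degree_mass.items()}
    trace = sum(counts.get((i, i), 0) for i in range(n_blocks)) / (2 * m)
    q = trace - sum(v * v for v in share.values())
    return PartitionSummary(
        module_count=n_blocks,
        mixing_fraction=e,
        module_link_share=share,
        trace=trace,
        q_value=q,
    )


# ---------------------------------------------------------------------------
# Clique percolation (CPM)


def _cpm_communities(g: nx.Graph, k: int) -> list[frozenset[str]]:
    return [frozenset(c) for c in nx.community.k_clique_communities(g, k)]


def detect_cpm(network: InteractionNetwork, k: int) -> list[Module]:
    """k-clique percolation communities (union of adjacent k-cliques).

    Two k-cliques are adjacent when they share k-1 nodes; a community is the
    node union of a maximal connected set of k-cliques.  Communities may
    overlap in fewer than k-1 nodes.  rank_score is the member count.
    """
    if k < 3:
        raise ValueError("clique percolation requires k >= 3")
    comms = _cpm_communities(network.graph, k)
    return assign_module_ids(
        [(c, float(len(c)), k) for c in comms], CPM, network.class_label
    )


# ---------------------------------------------------------------------------
# MCODE


def _vertex_weight(g: nx.Graph, v: str) -> float:
    """MCODE vertex weight: core number of the closed neighborhood graph
    times the density of that neighborhood's highest-order core."""
    nbhd = set(g[v]) | {v}
    h = g.subgraph(nbhd)
    if h.number_of_edges() == 0:
        return 0.0
    core = nx.core_number(h)
    kmax = max(core.values())
    top = [u for u, c in core.items() if c >= kmax]
    hk = h.subgraph(top)
    n = hk.number_of_nodes()
    if n < 2:
        return 0.0
    density = 2.0 * hk.number_of_edges() / (n * (n - 1))
    return kmax * density


def _neighborhood_density(g: nx.Graph, v: str) -> float:
    nbhd = set(g[v]) | {v}
    n = len(nbhd)
    if n < 2:
        return 0.0
    h = g.subgraph(nbhd)
    return 2.0 * h.number_of_edges() / (n * (n - 1))


def detect_mcode(
    network: InteractionNetwork, params: Optional[DetectionParams] = None
) -> list[Module]:
    """Greedy growth of vertex-weighted cores (Molecular Complex Detection).

    Seeds are taken in decreasing vertex weight; breadth-first growth admits
    unvisited neighbors whose weight is at least
    ``(1 - node_score_cutoff) * seed weight`` down to ``max_depth``.  The
    haircut step reduces each module to its 2-core, so every surviving member
    has at least two intra-module neighbors; fluff (off by default) adds
    boundary neighbors with dense neighborhoods and may create overlaps.

    rank_score = intra-module edges / members; k_param = the largest c such
    that every member keeps intra-module degree >= c (the module's coreness).
    """
    params = params or DetectionParams()
    g = network.graph
    weights = {v: _vertex_weight(g, v) for v in g.nodes}
    order = sorted(g.nodes, key=lambda v: (-weights[v], v))
    visited: set[str] = set()
    raw: list[set[str]] = []
    for seed in order:
        if seed in visited:
            continue
        threshold = (1.0 - params.mcode_node_score_cutoff) * weights[seed]
        members = {seed}
        visited.add(seed)
        frontier = [seed]
        depth = 0
        while frontier and depth < params.mcode_max_depth:
            nxt = []
            for u in frontier:
                for w in sorted(g[u]):
                    if w in visited or w in members:
                        continue
                    if weights[w] >= threshold:
                        members.add(w)
                        visited.add(w)
                        nxt.append(w)
            frontier = nxt
            depth += 1
        raw.append(members)

    results: list[tuple[frozenset[str], float, Optional[int]]] = []
    for members in raw:
        if params.mcode_haircut:
            sub = g.subgraph(members)
            members = set(nx.k_core(sub, 2).nodes)
        if params.mcode_fluff and members:
            extra = set()
            for u in members:
                for w in g[u]:
                    if w not in members and _neighborhood_density(g, w) >= (
                        params.mcode_fluff_density
                    ):
                        extra.add(w)
            members |= extra
        if len(members) < 2:
            continue
        sub = g.subgraph(members)
        n_edges = sub.number_of_edges()
        score = n_edges / len(members)
        coreness = min(dict(sub.degree).values())
        results.append((frozenset(members), score, coreness))
    return assign_module_ids(results, MCODE, network.class_label)


# ---------------------------------------------------------------------------
# Greedy modularity maximization (MaxMod)


def detect_greedy(
    network: InteractionNetwork,
) -> tuple[list[Module], PartitionSummary]:
    """Agglomerative modularity maximization.

    Starts from singleton modules and repeatedly merges the connected module
    pair whose amalgamation yields the largest increase in Q (ties broken by
    the lexicographically smallest module-id pair, where a module's id is its
    smallest member).  Stops when no merge increases Q and returns the
    partition of maximal Q encountered.  Singleton communities never become
    modules but still enter the partition summary.
    """
    g = network.graph
    m = g.number_of_edges()
    if m == 0:
        raise ValueError("greedy modularity requires at least one edge")

    comm: dict[str, set[str]] = {v: {v} for v in g.nodes}
    # b[i][j]: fraction of edges between communities i and j (i != j)
    b: dict[str, dict[str, float]] = {v: {} for v in g.nodes}
    intra: dict[str, float] = {v: 0.0 for v in g.nodes}
    share: dict[str, float] = {v: g.degree(v) / (2.0 * m) for v in g.nodes}
    for u, v in g.edges:
        b[u][v] = b[u].get(v, 0.0) + 1.0 / m
        b[v][u] = b[v].get(u, 0.0) + 1.0 / m

    while True:
        best = None
        for i in sorted(b):
            for j in sorted(b[i]):
                if j <= i:
                    continue
                dq = b[i][j] - 2.0 * share[i] * share[j]
                if best is None or dq > best[0] + _TOL or (
                    abs(dq - best[0]) <= _TOL and (i, j) < (best[1], best[2])
                ):
                    best = (dq, i, j)
        if best is None or best[0] <= _TOL:
            break
        _, i, j = best
        # merge j into i; community id stays the smallest member (i < j)
        intra[i] += intra[j] + b[i].pop(j)
        del b[j][i]
        for k, w in b[j].items():
            b[i][k] = b[i].get(k, 0.0) + w
            del b[k][j]
            b[k][i] = b[k].get(i, 0.0) + w
        share[i] += share[j]
        comm[i] |= comm[j]
        del b[j], share[j], intra[j], comm[j]

    blocks = [comm[i] for i in sorted(comm)]
    summary = modularity_q(network, blocks)
    modules = assign_module_ids(
        [
            (frozenset(c), float(len(c)), None)
            for c in blocks
            if len(c) > 1
        ],
        MAXMOD,
        network.class_label,
    )
    return modules, summary


# ---------------------------------------------------------------------------
# Walktrap


def _walktrap_component(
    g: nx.Graph, nodes: list[str], steps: int
) -> list[list[set[str]]]:
    """Merge sequence (list of partitions) for one connected component.

    Implements t-step random-walk distances with degree-normalized
    components and Ward-style agglomeration of adjacent communities.
    """
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    a = nx.to_numpy_array(g, nodelist=nodes)
    deg = a.sum(axis=1)
    p = a / deg[:, None]
    pt = np.linalg.matrix_power(p, steps)
    inv_sqrt_d = 1.0 / np.sqrt(deg)

    comms: dict[int, set[str]] = {i: {v} for i, v in enumerate(nodes)}
    prof: dict[int, np.ndarray] = {i: pt[i] for i in range(n)}
    adjacency: dict[int, set[int]] = {
        i: {idx[u] for u in g[nodes[i]]} for i in range(n)
    }

    def dist2(ci: int, cj: int) -> float:
        diff = (prof[ci] - prof[cj]) * inv_sqrt_d
        return float(diff @ diff)

    partitions = [[set(c) for c in comms.values()]]
    while len(comms) > 1:
        best = None
        for i in sorted(comms):
            for j in sorted(adjacency[i]):
                if j <= i or j not in comms:
                    continue
                ni, nj = len(comms[i]), len(comms[j])
                dsig = (ni * nj / (ni + nj)) * dist2(i, j) / n
                key = (dsig, min(sorted(comms[i])[0], sorted(comms[j])[0]))
                if best is None or dsig < best[0] - _TOL or (
                    abs(dsig - best[0]) <= _TOL and key[1] < best[3]
                ):
                    best = (dsig, i, j, key[1])
        if best is None:
            break
        _, i, j, _ = best
        ni, nj = len(comms[i]), len(comms[j])
        prof[i] = (ni * prof[i] + nj * prof[j]) / (ni + nj)
        comms[i] |= comms[j]
        adjacency[i] = (adjacency[i] | adjacency[j]) - {i, j}
        for k in adjacency[j]:
            adjacency[k].discard(j)
            if k != i:
                adjacency[k].add(i)
                adjacency[i].add(k)
        del comms[j], prof[j], adjacency[j]
        partitions.append([set(c) for c in comms.values()])
    return partitions


def detect_walktrap(
    network: InteractionNetwork, steps: int = 4
) -> tuple[list[Module], PartitionSummary]:
    """Random-walk agglomerative community detection.

    Each connected component is agglomerated independently along the Ward
    merge tree of t-step transition-probability distances; within each
    component the cut with maximal Q is retained (Q decomposes over
    communities, so per-component optimization maximizes the global Q).
    """
    if steps < 1:
        raise ValueError("walktrap requires steps >= 1")
    g = network.graph
    m = g.number_of_edges()
    if m == 0:
        raise ValueError("walktrap requires at least one edge")

    def q_contrib(block: set[str]) -> float:
        sub = g.subgraph(block)
        d = sum(g.degree(v) for v in block)
        return sub.number_of_edges() / m - (d / (2.0 * m)) ** 2

    blocks: list[set[str]] = []
    for component in sorted(nx.connected_components(g), key=lambda c: sorted(c)[0]):
        nodes = sorted(component)
        if len(nodes) == 1:
            blocks.append(set(nodes))
            continue
        partitions = _walktrap_component(g, nodes, steps)
        best = max(
            partitions, key=lambda part: sum(q_contrib(bl) for bl in part)
        )
        blocks.extend(best)

    summary = modularity_q(network, blocks)
    modules = assign_module_ids(
        [(frozenset(c), float(len(c)), None) for c in blocks if len(c) > 1],
        WALKTRAP,
        network.class_label,
    )
    return modules, summary


# ---------------------------------------------------------------------------
# Community selection and census


def select_cfinder_communities(
    modules_by_k: Mapping[int, Sequence[Module]],
    params: Optional[DetectionParams] = None,
) -> list[Module]:
    """Two-step reduction of k-clique communities.

    Forward: for each k >= 4, discard communities larger than
    ``max_community_size`` and keep at most ``representative_subset_size``
    communities closest to the median size for that k (stable tie-break on
    module_id).  Backward, from the largest k down: keep a community only if
    its member set is not a subset of an already selected one.  The result is
    ordered by decreasing k, then decreasing size.
    """
    params = params or DetectionParams()
    survivors: dict[int, list[Module]] = {}
    for k in sorted(modules_by_k):
        if k < 4:
            continue
        mods = [
            m for m in modules_by_k[k] if m.size <= params.max_community_size
        ]
        if not mods:
            continue
        med = median(m.size for m in mods)
        mods.sort(key=lambda m: (abs(m.size - med), m.module_id))
        survivors[k] = mods[: params.representative_subset_size]

    selected: list[Module] = []
    for k in sorted(survivors, reverse=True):
        for mod in sorted(survivors[k], key=lambda m: (-m.size, m.module_id)):
            if any(mod.members <= s.members for s in selected):
                continue
            selected.append(mod)
    return selected


def size_histogram(modules: Iterable[Module]) -> dict[int, int]:
    """Exact census of module sizes: {size: count}."""
    return dict(Counter(m.size for m in modules))
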