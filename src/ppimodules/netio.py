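"""Data model for interactome classes and readers/writers for the pipeline's file formats.

An *interactome class* is an undirected, simple protein-protein interaction
network built from one evidence source: literature curation (LIT), orthology
transfer (ORTHO), high-throughput screens (HTP), or their union (INT).
All downstream detectors and scoring operate on :class:`InteractionNetwork`
and produce :class:`Module` records.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx

logger = logging.getLogger("ppimodules")

# Canonical class labels.  Synthetic networks may use "SYNTHETIC-<tag>".
LIT = "LIT"
ORTHO = "ORTHO"
HTP = "HTP"
INT = "INT"

#: Module-id prefixes in the conventional spelling used in result tables.
_PREFIXES = {LIT: "Lit", ORTHO: "Ortho", HTP: "HTP", INT: "Int"}

#: The four detection methods.
CPM = "CPM"
MCODE = "MCODE"
MAXMOD = "MAXMOD"
WALKTRAP = "WALKTRAP"


def module_prefix(class_label: str) -> str:
    """Human-readable prefix for module ids of a class ("LIT" -> "Lit")."""
    return _PREFIXES.get(class_label, class_label)


class ParseError(ValueError):
    """Raised for malformed input files; names the offending line."""


@dataclass
class InteractionNetwork:
    """An undirected simple graph of protein identifiers with a class label.

    Invariants: no self-loops, no duplicate edges, edges reference existing
    nodes; (a, b) and (b, a) are the same edge.  Isolated nodes are allowed
    (they matter for coverage bookkeeping) but never appear in modules.
    """

    class_label: str
    graph: nx.Graph = field(default_factory=nx.Graph)

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str]],
        class_label: str,
        nodes: Iterable[str] = (),
    ) -> "InteractionNetwork":
        g = nx.Graph()
        g.add_nodes_from(nodes)
        for a, b in edges:
            if a == b:
                continue
            g.add_edge(a, b)
        return cls(class_label=class_label, graph=g)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[frozenset[str]]:
        return {frozenset(e) for e in self.graph.edges}

    def number_of_nodes(self) -> int:
        return self.graph.number_of_nodes()

    def number_of_edges(self) -> int:
        return self.graph.number_of_edges()

    def degree(self, node: str) -> int:
        return self.graph.degree(node)


@dataclass(frozen=True)
class Module:
    """A set of proteins produced by one detector from one interactome class.

    ``module_id`` has the form ``<class>-<ordinal>`` (e.g. ``"Lit-9"``) and is
    unique within one (method, class) run.  ``k_param`` is the clique size for
    CPM or the core degree for MCODE; ``rank_score`` is the method-specific
    ordering key (non-negative).
    """

    module_id: str
    members: frozenset[str]
    method: str
    k_param: Optional[int] = None
    rank_score: float = 0.0

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"module {self.module_id!r} has no members")
        if self.rank_score < 0:
            raise ValueError("rank_score must be non-negative")

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def class_label(self) -> str:
        """Class prefix encoded in the module id ('Lit-9' -> 'Lit')."""
        return self.module_id.rsplit("-", 1)[0]


def assign_module_ids(
    member_sets: Sequence[tuple[frozenset[str], float, Optional[int]]],
    method: str,
    class_label: str,
) -> list[Module]:
    """Build Module records with deterministic ordinals.

    Ordinals are assigned by rank_score descending, then lexicographic member
    order, so identical inputs always yield identical module ids.
    """
    prefix = module_prefix(class_label)
    ordered = sorted(
        member_sets, key=lambda t: (-t[1], tuple(sorted(t[0])))
    )
    return [
        Module(
            module_id=f"{prefix}-{i + 1}",
            members=members,
            method=method,
            k_param=k,
            rank_score=score,
        )
        for i, (members, score, k) in enumerate(ordered)
    ]


# ---------------------------------------------------------------------------
# Edge lists


def load_edgelist(
    path: str | Path, class_label: str, fmt: str = "edgelist"
) -> InteractionNetwork:
    """Read a tab-delimited edge list (or 3-column SIF) into a network.

    ``fmt='edgelist'``: the first two columns are protein identifiers (extra
    columns ignored).  ``fmt='sif'``: columns are (node, interaction type,
    node); the middle column is ignored.  Lines starting with '#' are
    comments.  Self-loops and duplicate edges are dropped with a logged count.
    """
    if fmt not in ("edgelist", "sif"):
        raise ValueError(f"unknown edge-list format {fmt!r}")
    path = Path(path)
    g = nx.Graph()
    self_loops = 0
    duplicates = 0
    n_lines = 0
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) == 1:
                cols = line.split()
            need = 3 if fmt == "sif" else 2
            if len(cols) < need:
                raise ParseError(
                    f"{path}: line {lineno}: expected >= {need} columns, "
                    f"got {len(cols)}"
                )
            a = cols[0].strip()
            b = (cols[2] if fmt == "sif" else cols[1]).strip()
            if not a or not b:
                raise ParseError(f"{path}: line {lineno}: empty identifier")
            n_lines += 1
            if a == b:
                self_loops += 1
                g.add_node(a)
                continue
            if g.has_edge(a, b):
                duplicates += 1
                continue
            g.add_edge(a, b)
    if n_lines == 0:
        raise ParseError(f"{path}: no interaction records found")
    logger.info(
        "loaded %s: %d nodes, %d edges (%d self-loops and %d duplicates dropped)",
        path,
        g.number_of_nodes(),
        g.number_of_edges(),
        self_loops,
        duplicates,
    )
    return InteractionNetwork(class_label=class_label, graph=g)


def write_edgelist(network: InteractionNetwork, path: str | Path) -> None:
    """Write a 2-column TSV edge list (sorted; isolated nodes as comments)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# class: {network.class_label}\n")
        isolated = sorted(n for n in network.graph.nodes if network.graph.degree(n) == 0)
        for n in isolated:
            fh.write(f"# isolated: {n}\n")
        for a, b in sorted(tuple(sorted(e)) for e in network.graph.edges):
            fh.write(f"{a}\t{b}\n")


def integrate(networks: Sequence[InteractionNetwork]) -> InteractionNetwork:
    """Fuse interactome classes into the integrated class (node/edge union).

    Set semantics make this commutative, associative and idempotent.
    """
    if not networks:
        raise ValueError("integrate requires at least one network")
    g = nx.Graph()
    for net in networks:
        g.add_nodes_from(net.graph.nodes)
        g.add_edges_from(net.graph.edges)
    return InteractionNetwork(class_label=INT, graph=g)


# ---------------------------------------------------------------------------
# Module tables

_MODULE_HEADER = ["module_id", "method", "class", "k_param", "rank_score", "members"]


def write_modules(modules: Iterable[Module], path: str | Path) -> None:
    """Write modules as a TSV table that round-trips through read_modules."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_MODULE_HEADER)
        for m in modules:
            w.writerow(
                [
                    m.module_id,
                    m.method,
                    m.class_label,
                    "" if m.k_param is None else m.k_param,
                    repr(float(m.rank_score)),
                    ";".join(sorted(m.members)),
                ]
            )


def read_modules(path: str | Path) -> list[Module]:
    """Read a module table written by :func:`write_modules`."""
    path = Path(path)
    modules = []
    with path.open() as fh:
        r = csv.reader(fh, delimiter="\t")
        header = next(r, None)
        if header is None:
            raise ParseError(f"{path}: empty module table")
        if header != _MODULE_HEADER:
            raise ParseError(f"{path}: unexpected header {header!r}")
        for lineno, row in enumerate(r, start=2):
            if not row:
                continue
            if len(row) != len(_MODULE_HEADER):
                raise ParseError(f"{path}: line {lineno}: wrong column count")
            module_id, method, _cls, k, score, members = row
            modules.append(
                Module(
                    module_id=module_id,
                    members=frozenset(members.split(";")),
                    method=method,
                    k_param=int(k) if k else None,
                    rank_score=float(score),
                )
            )
    return modules


# ---------------------------------------------------------------------------
# Gene-set catalogs (GMT), annotation tables, expression matrices


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT catalog (set-id, description, members...) -> {id: members}."""
    path = Path(path)
    sets: dict[str, set[str]] = {}
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise ParseError(
                    f"{path}: line {lineno}: GMT rows need id, description and members"
                )
            sets[cols[0]] = {c for c in cols[2:] if c}
    return sets


def write_gmt(
    sets: Mapping[str, Iterable[str]],
    path: str | Path,
    descriptions: Optional[Mapping[str, str]] = None,
) -> None:
    """Write gene sets in GMT format (tab-separated, one set per row)."""
    path = Path(path)
    with path.open("w") as fh:
        for name in sorted(sets):
            desc = (descriptions or {}).get(name, "na")
            members = "\t".join(sorted(sets[name]))
            fh.write(f"{name}\t{desc}\t{members}\n")


def read_annotations(path: str | Path) -> dict[str, set[str]]:
    """Read a 2-column TSV protein -> term table (one row per assignment)."""
    path = Path(path)
    assignments: dict[str, set[str]] = {}
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 2:
                raise ParseError(f"{path}: line {lineno}: expected 2 columns")
            assignments.setdefault(cols[0], set()).add(cols[1])
    return assignments


def write_annotations(assignments: Mapping[str, Iterable[str]], path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for protein in sorted(assignments):
            for term in sorted(assignments[protein]):
                fh.write(f"{protein}\t{term}\n")
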