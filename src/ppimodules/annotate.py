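"""Module-level annotation variables from GO-style ontologies and expression.

For every module the seven variables used by the confidence scheme are
computed:

* ``n`` — number of proteins in the module,
* ``n_ex`` — members present in the expression matrix,
* ``ex_mean`` — pooled mean expression over those members and all tissues,
* ``cor_mean`` — mean pairwise Spearman correlation of tissue profiles over
  all unordered pairs of expressed members,
* ``mf_mean`` / ``bp_mean`` / ``cc_mean`` — mean co-annotation over
  intra-module interacting pairs, one value per GO namespace.

Co-annotation of two proteins is the Jaccard similarity of their ancestor
graphs: the is_a closure of their assigned terms in one namespace, with the
namespace root excluded (the root is shared by every annotated protein and
would put a floor under every similarity).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import obonet
import pandas as pd
from scipy import stats

from .netio import InteractionNetwork, Module

NAMESPACES = ("MF", "BP", "CC")

_OBO_NAMESPACES = {
    "molecular_function": "MF",
    "biological_process": "BP",
    "cellular_component": "CC",
}
_OBO_NAMES = {v: k for k, v in _OBO_NAMESPACES.items()}


@dataclass
class OntologyDag:
    """A three-namespace is_a DAG with one root per namespace."""

    parents: dict[str, set[str]]
    namespace: dict[str, str]
    roots: dict[str, str]
    _ancestor_cache: dict[str, frozenset[str]] = field(
        default_factory=dict, repr=False
    )

    @property
    def terms(self) -> set[str]:
        return set(self.namespace)

    def ancestors(self, term: str) -> frozenset[str]:
        """All is_a ancestors of ``term`` (excluding the term itself)."""
        cached = self._ancestor_cache.get(term)
        if cached is not None:
            return cached
        acc: set[str] = set()
        stack = list(self.parents.get(term, ()))
        while stack:
            t = stack.pop()
            if t in acc:
                continue
            acc.add(t)
            stack.extend(self.parents.get(t, ()))
        result = frozenset(acc)
        self._ancestor_cache[term] = result
        return result

    def validate(self) -> None:
        for ns in NAMESPACES:
            if ns not in self.roots:
                raise ValueError(f"missing root for namespace {ns}")
        for term, ns in self.namespace.items():
            root = self.roots[ns]
            if term != root and root not in self.ancestors(term):
                raise ValueError(f"term {term} does not reach its root {root}")


@dataclass
class AnnotationMap:
    """protein -> set of assigned ontology terms (any namespace)."""

    assignments: dict[str, set[str]]

    def terms_for(self, protein: str) -> set[str]:
        return self.assignments.get(protein, set())


@dataclass
class ExpressionMatrix:
    """protein x tissue expression scores (platform units, log scale)."""

    values: pd.DataFrame  # index: proteins, columns: tissues

    @property
    def proteins(self) -> list[str]:
        return list(self.values.index)

    @property
    def tissues(self) -> list[str]:
        return list(self.values.columns)

    def __contains__(self, protein: str) -> bool:
        return protein in self.values.index

    def profile(self, protein: str) -> np.ndarray:
        return self.values.loc[protein].to_numpy(dtype=float)


@dataclass(frozen=True)
class ModuleVariables:
    """The seven per-module quantities feeding confidence assignment.

    ``cor_mean`` is absent (None) when fewer than two members are in the
    expression matrix; a GO mean is absent when no intra-module interacting
    pair has nonempty ancestor graphs in that namespace.
    """

    module_id: str
    n: int
    n_ex: int
    ex_mean: Optional[float]
    cor_mean: Optional[float]
    mf_mean: Optional[float]
    bp_mean: Optional[float]
    cc_mean: Optional[float]


# ---------------------------------------------------------------------------
# Ontology I/O


def load_obo(path: str | Path) -> OntologyDag:
    """Read an OBO 1.2 flat file (is_a relations only) into an OntologyDag."""
    graph = obonet.read_obo(str(path))
    parents: dict[str, set[str]] = {}
    namespace: dict[str, str] = {}
    for term, data in graph.nodes(data=True):
        ns = _OBO_NAMESPACES.get(data.get("namespace", ""))
        if ns is None:
            continue
        namespace[term] = ns
        parents.setdefault(term, set())
    for child, parent, rel in graph.edges(keys=True):
        if rel == "is_a" and child in namespace and parent in namespace:
            parents[child].add(parent)
    roots: dict[str, str] = {}
    for term, ns in namespace.items():
        if not parents[term]:
            if ns in roots:
                raise ValueError(f"namespace {ns} has more than one root")
            roots[ns] = term
    dag = OntologyDag(parents=parents, namespace=namespace, roots=roots)
    dag.validate()
    return dag


def write_obo(ontology: OntologyDag, path: str | Path) -> None:
    """Write the DAG as a minimal OBO 1.2 flat file."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("format-version: 1.2\n")
        fh.write("ontology: synthetic\n")
        for term in sorted(ontology.namespace):
            ns = ontology.namespace[term]
            fh.write("\n[Term]\n")
            fh.write(f"id: {term}\n")
            fh.write(f"name: {term}\n")
            fh.write(f"namespace: {_OBO_NAMES[ns]}\n")
            for parent in sorted(ontology.parents.get(term, ())):
                fh.write(f"is_a: {parent} ! {parent}\n")


def load_annotation_map(
    path: str | Path, ontology: Optional[OntologyDag] = None
) -> AnnotationMap:
    """Read a 2-column protein -> term TSV, optionally checking terms exist."""
    from .netio import read_annotations

    assignments = read_annotations(path)
    if ontology is not None:
        known = ontology.terms
        for protein, terms in assignments.items():
            unknown = terms - known
            if unknown:
                raise ValueError(
                    f"protein {protein} annotated to unknown terms {sorted(unknown)}"
                )
    return AnnotationMap(assignments=assignments)


def load_expression(path: str | Path) -> ExpressionMatrix:
    """Read a TSV expression table (first column protein id, rest tissues)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.isna().any().any():
        raise ValueError(f"{path}: expression matrix contains missing values")
    return ExpressionMatrix(values=df.astype(float))


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="protein", float_format="%.6f")


# ---------------------------------------------------------------------------
# Co-annotation


def ancestor_graph(
    protein: str,
    namespace: str,
    ontology: OntologyDag,
    annotations: AnnotationMap,
) -> frozenset[str]:
    """Assigned terms of ``protein`` in ``namespace`` plus all is_a ancestors,
    excluding the namespace root.  Empty if the protein is unannotated there.
    """
    if namespace not in NAMESPACES:
        raise ValueError(f"unknown namespace {namespace!r}")
    root = ontology.roots.get(namespace)
    terms: set[str] = set()
    for t in annotations.terms_for(protein):
        if ontology.namespace.get(t) != namespace:
            continue
        terms.add(t)
        terms |= ontology.ancestors(t)
    terms.discard(root)
    return frozenset(terms)


def coannotation_similarity(
    p1: str,
    p2: str,
    namespace: str,
    ontology: OntologyDag,
    annotations: AnnotationMap,
) -> Optional[float]:
    """Jaccard similarity of two proteins' ancestor graphs in one namespace.

    Returns None when either ancestor graph is empty.
    """
    a = ancestor_graph(p1, namespace, ontology, annotations)
    b = ancestor_graph(p2, namespace, ontology, annotations)
    if not a or not b:
        return None
    return len(a & b) / len(a | b)


# ---------------------------------------------------------------------------
# Spearman correlation and module variables


def spearman(x: Sequence[float], y: Sequence[float]) -> Optional[float]:
    """Spearman rank correlation (midranks for ties).

    Returns None for vectors shorter than 3 or with zero rank variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    if x.size < 3:
        return None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", stats.ConstantInputWarning)
        rho = stats.spearmanr(x, y).statistic
    if np.isnan(rho):
        return None
    return float(rho)


def module_variables(
    module: Module,
    ontology: OntologyDag,
    annotations: AnnotationMap,
    expression: ExpressionMatrix,
    network: InteractionNetwork,
) -> ModuleVariables:
    """Compute the seven annotation variables for one module.

    GO means average co-annotation over intra-module network edges (pairs of
    interacting members); pairs with an empty ancestor graph are dropped from
    the mean.  cor_mean averages Spearman correlations over all unordered
    pairs of expressed members; zero-rank-variance pairs are dropped.  Values
    are kept at full precision; rounding happens only at presentation.
    """
    members = sorted(module.members)
    missing = module.members - network.nodes
    if missing:
        raise ValueError(f"module members not in network: {sorted(missing)[:5]}")

    expressed = [p for p in members if p in expression]
    n_ex = len(expressed)
    if n_ex:
        block = expression.values.loc[expressed].to_numpy(dtype=float)
        ex_mean = float(block.mean())
    else:
        ex_mean = None

    cor_mean: Optional[float] = None
    if n_ex >= 2:
        cors = []
        for i in range(n_ex):
            xi = expression.profile(expressed[i])
            for j in range(i + 1, n_ex):
                rho = spearman(xi, expression.profile(expressed[j]))
                if rho is not None:
                    cors.append(rho)
        if cors:
            cor_mean = float(np.mean(cors))

    g = network.graph
    member_set = module.members
    intra_edges = [
        (u, v) for u, v in g.edges(members) if u in member_set and v in member_set
    ]
    go_means: dict[str, Optional[float]] = {}
    for ns in NAMESPACES:
        graphs = {
            p: ancestor_graph(p, ns, ontology, annotations) for p in members
        }
        sims = []
        for u, v in intra_edges:
            a, b = graphs[u], graphs[v]
            if not a or not b:
                continue
            sims.append(len(a & b) / len(a | b))
        go_means[ns] = float(np.mean(sims)) if sims else None

    return ModuleVariables(
        module_id=module.module_id,
        n=len(members),
        n_ex=n_ex,
        ex_mean=ex_mean,
        cor_mean=cor_mean,
        mf_mean=go_means["MF"],
        bp_mean=go_means["BP"],
        cc_mean=go_means["CC"],
    )
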