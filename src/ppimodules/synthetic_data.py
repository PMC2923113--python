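"""Synthetic inputs with the statistical structure the pipeline assumes.

One ground-truth interactome is built from densely wired planted modules
over a sparse random background.  Each interactome class samples the truth
with a class-specific edge-retention rate and adds class-specific spurious
edges, emulating evidence sources of different coverage and accuracy
(literature curation best, high-throughput screens noisiest); the
integrated class is their union.  On top of the truth the generator
produces a three-namespace ontology with module-coherent annotations,
tissue expression with high within-module correlation for permanent plants
and low for transient ones, and complex/pathway catalogs that are perturbed
copies of the plants.

All generators are pure functions of (spec, seed): outputs are byte
identical across runs.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import numpy as np

from .annotate import AnnotationMap, ExpressionMatrix, OntologyDag, NAMESPACES
from .netio import HTP, INT, LIT, ORTHO, InteractionNetwork, integrate
from .score import PERMANENT, TRANSIENT

import pandas as pd


def _default_retention() -> dict[str, float]:
    return {LIT: 0.9, ORTHO: 0.7, HTP: 0.4}


def _default_noise() -> dict[str, float]:
    return {LIT: 0.02, ORTHO: 0.05, HTP: 0.15}


@dataclass(frozen=True)
class PlantSpec:
    """Study conditions for the synthetic interactome classes.

    Defaults: 8 disjoint plants of 6–12 proteins wired at density 0.9 over a
    300-node background of density 0.005; class retention LIT 0.9 / ORTHO
    0.7 / HTP 0.4 with spurious-edge rates 0.02 / 0.05 / 0.15; half of the
    plants permanent.
    """

    n_plants: int = 8
    plant_size_range: tuple[int, int] = (6, 12)
    intra_density: float = 0.9
    background_nodes: int = 300
    background_density: float = 0.005
    class_edge_retention: Mapping[str, float] = field(
        default_factory=_default_retention
    )
    class_extra_noise: Mapping[str, float] = field(default_factory=_default_noise)
    permanent_fraction: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        lo, hi = self.plant_size_range
        if lo < 3 or hi < lo:
            raise ValueError("plant sizes must satisfy 3 <= lo <= hi")
        if not 0.0 < self.intra_density <= 1.0:
            raise ValueError("intra_density must lie in (0, 1]")
        if self.intra_density <= self.background_density:
            raise ValueError("intra_density must exceed background_density")
        if self.background_nodes < 0:
            raise ValueError("background_nodes must be non-negative")
        if self.n_plants < 1:
            raise ValueError("need at least one plant")
        for label, r in self.class_edge_retention.items():
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"retention for {label} outside [0, 1]")
        if not 0.0 <= self.permanent_fraction <= 1.0:
            raise ValueError("permanent_fraction must lie in [0, 1]")


@dataclass
class GroundTruth:
    """Planted modules, their permanence classes, and the true interactome."""

    plants: dict[str, set[str]]
    permanence: dict[str, str]
    true_network: InteractionNetwork

    @property
    def plant_proteins(self) -> set[str]:
        out: set[str] = set()
        for members in self.plants.values():
            out |= members
        return out

    def to_json(self, path: str | Path) -> None:
        payload = {
            "plants": {k: sorted(v) for k, v in sorted(self.plants.items())},
            "permanence": dict(sorted(self.permanence.items())),
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def generate_interactome_classes(
    spec: Optional[PlantSpec] = None,
) -> tuple[GroundTruth, dict[str, InteractionNetwork]]:
    """Build the ground truth and one network per interactome class.

    The true network wires every within-plant pair with ``intra_density``
    and all remaining pairs with ``background_density``.  Each disaggregated
    class keeps true edges independently at its retention rate and adds
    spurious non-edges at its noise rate (relative to the kept edge count);
    the INT class is the union of the disaggregated classes.
    """
    spec = spec or PlantSpec()
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    lo, hi = spec.plant_size_range
    sizes = [int(rng.integers(lo, hi + 1)) for _ in range(spec.n_plants)]
    n_total = sum(sizes) + spec.background_nodes
    proteins = [f"P{i:04d}" for i in range(n_total)]

    plants: dict[str, set[str]] = {}
    cursor = 0
    for i, size in enumerate(sizes, start=1):
        plants[f"plant-{i}"] = set(proteins[cursor : cursor + size])
        cursor += size

    n_perm = int(round(spec.n_plants * spec.permanent_fraction))
    order = rng.permutation(sorted(plants))
    permanence = {
        name: (PERMANENT if i < n_perm else TRANSIENT)
        for i, name in enumerate(order)
    }

    plant_of: dict[str, str] = {}
    for name, members in plants.items():
        for p in members:
            plant_of[p] = name

    true_edges: list[tuple[str, str]] = []
    for a, b in itertools.combinations(proteins, 2):
        same_plant = plant_of.get(a) is not None and plant_of.get(a) == plant_of.get(b)
        prob = spec.intra_density if same_plant else spec.background_density
        if rng.random() < prob:
            true_edges.append((a, b))
    true_network = InteractionNetwork.from_edges(
        true_edges, class_label="SYNTHETIC-TRUTH", nodes=proteins
    )

    edge_index = {e: i for i, e in enumerate(true_edges)}
    classes: dict[str, InteractionNetwork] = {}
    for label in (LIT, ORTHO, HTP):
        retention = spec.class_edge_retention.get(label, 1.0)
        noise = spec.class_extra_noise.get(label, 0.0)
        keep_mask = rng.random(len(true_edges)) < retention
        kept = [e for e, keep in zip(true_edges, keep_mask) if keep]
        n_extra = int(round(noise * len(kept)))
        extra: list[tuple[str, str]] = []
        seen = set(map(frozenset, kept))
        while len(extra) < n_extra:
            i, j = rng.integers(0, n_total, size=2)
            if i == j:
                continue
            a, b = proteins[int(i)], proteins[int(j)]
            key = frozenset((a, b))
            if key in seen or (a, b) in edge_index or (b, a) in edge_index:
                continue
            seen.add(key)
            extra.append((a, b))
        classes[label] = InteractionNetwork.from_edges(
            kept + extra, class_label=label, nodes=proteins
        )
    int_net = integrate([classes[LIT], classes[ORTHO], classes[HTP]])
    classes[INT] = int_net

    truth = GroundTruth(
        plants=plants, permanence=permanence, true_network=true_network
    )
    return truth, classes


# ---------------------------------------------------------------------------
# Annotation layer


def _random_tree(
    prefix: str, depth: int, branching: int
) -> tuple[dict[str, set[str]], list[str], str]:
    """A rooted is_a tree; returns (parents, leaves, root)."""
    counter = 0

    def new_term() -> str:
        nonlocal counter
        term = f"{prefix}:{counter:07d}"
        counter += 1
        return term

    root = new_term()
    parents: dict[str, set[str]] = {root: set()}
    level = [root]
    for _ in range(depth):
        nxt = []
        for parent in level:
            for _ in range(branching):
                child = new_term()
                parents[child] = {parent}
                nxt.append(child)
        level = nxt
    return parents, level, root


def generate_annotation_layer(
    truth: GroundTruth,
    depth: int = 4,
    p_coherent: float = 0.9,
    p_noise: float = 0.05,
    seed: int = 0,
    branching: int = 3,
) -> tuple[OntologyDag, AnnotationMap]:
    """Three random is_a trees plus module-coherent leaf annotations.

    Every plant is assigned a home leaf per namespace; each member gets the
    home leaf with probability ``p_coherent``, a uniformly random leaf with
    probability ``p_noise``, and no annotation otherwise.  Background
    proteins get one uniformly random leaf per namespace.
    """
    if depth < 2:
        raise ValueError("ontology depth must be >= 2")
    if p_coherent + p_noise > 1.0:
        raise ValueError("p_coherent + p_noise must not exceed 1")
    rng = np.random.default_rng(seed)

    parents: dict[str, set[str]] = {}
    namespace: dict[str, str] = {}
    roots: dict[str, str] = {}
    leaves: dict[str, list[str]] = {}
    for ns in NAMESPACES:
        tree_parents, tree_leaves, root = _random_tree(ns, depth, branching)
        parents.update(tree_parents)
        namespace.update({t: ns for t in tree_parents})
        roots[ns] = root
        leaves[ns] = tree_leaves
    ontology = OntologyDag(parents=parents, namespace=namespace, roots=roots)

    assignments: dict[str, set[str]] = {}
    home_leaf = {
        (plant, ns): leaves[ns][int(rng.integers(len(leaves[ns])))]
        for plant in sorted(truth.plants)
        for ns in NAMESPACES
    }
    plant_members = truth.plant_proteins
    for plant in sorted(truth.plants):
        for protein in sorted(truth.plants[plant]):
            for ns in NAMESPACES:
                u = rng.random()
                if u < p_coherent:
                    term = home_leaf[(plant, ns)]
                elif u < p_coherent + p_noise:
                    term = leaves[ns][int(rng.integers(len(leaves[ns])))]
                else:
                    continue
                assignments.setdefault(protein, set()).add(term)
    for protein in sorted(truth.true_network.nodes - plant_members):
        for ns in NAMESPACES:
            term = leaves[ns][int(rng.integers(len(leaves[ns])))]
            assignments.setdefault(protein, set()).add(term)
    return ontology, AnnotationMap(assignments=assignments)


# ---------------------------------------------------------------------------
# Expression


def generate_expression(
    truth: GroundTruth,
    n_tissues: int = 50,
    rho_permanent: float = 0.8,
    rho_transient: float = 0.1,
    seed: int = 0,
    baseline: float = 8.0,
) -> ExpressionMatrix:
    """Correlated tissue expression profiles.

    Each plant carries a latent tissue profile; member profiles mix the
    latent signal and independent noise as sqrt(rho) * latent +
    sqrt(1 - rho) * noise, with rho set by the plant's permanence class,
    shifted to a positive log-scale baseline.  Background proteins are pure
    noise around the baseline.
    """
    if n_tissues < 10:
        raise ValueError("need at least 10 tissues")
    if not 0.0 <= rho_transient < rho_permanent <= 1.0:
        raise ValueError("require 0 <= rho_transient < rho_permanent <= 1")
    rng = np.random.default_rng(seed)
    tissues = [f"T{i:02d}" for i in range(1, n_tissues + 1)]

    rows: dict[str, np.ndarray] = {}
    for plant in sorted(truth.plants):
        latent = rng.standard_normal(n_tissues)
        rho = (
            rho_permanent
            if truth.permanence[plant] == PERMANENT
            else rho_transient
        )
        for protein in sorted(truth.plants[plant]):
            noise = rng.standard_normal(n_tissues)
            rows[protein] = (
                np.sqrt(rho) * latent + np.sqrt(1.0 - rho) * noise + baseline
            )
    for protein in sorted(truth.true_network.nodes - truth.plant_proteins):
        rows[protein] = rng.standard_normal(n_tissues) + baseline

    df = pd.DataFrame.from_dict(rows, orient="index", columns=tissues)
    df = df.sort_index()
    return ExpressionMatrix(values=df)


# ---------------------------------------------------------------------------
# Reference catalogs


def generate_catalogs(
    truth: GroundTruth,
    dropout: float = 0.1,
    contamination: float = 0.1,
    seed: int = 0,
) -> tuple[dict[str, set[str]], dict[str, set[str]]]:
    """Complex and pathway catalogs as perturbed copies of the plants.

    Each complex is a plant with members dropped independently at the
    dropout rate and background contaminants added at the contamination
    rate (never emptied completely).  Each pathway is the union of 1–3
    plants.
    """
    if not (0.0 <= dropout < 1.0 and 0.0 <= contamination < 1.0):
        raise ValueError("dropout and contamination must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    background = sorted(truth.true_network.nodes - truth.plant_proteins)

    complexes: dict[str, set[str]] = {}
    for i, plant in enumerate(sorted(truth.plants), start=1):
        members = sorted(truth.plants[plant])
        kept = [p for p in members if rng.random() >= dropout]
        if not kept:
            kept = [members[int(rng.integers(len(members)))]]
        n_cont = int(rng.binomial(len(members), contamination)) if background else 0
        contaminants = (
            [background[int(k)] for k in rng.choice(len(background), size=n_cont, replace=False)]
            if n_cont
            else []
        )
        complexes[f"complex-{i}"] = set(kept) | set(contaminants)

    pathways: dict[str, set[str]] = {}
    plant_names = sorted(truth.plants)
    i = 0
    p_idx = 1
    while i < len(plant_names):
        group_size = int(rng.integers(1, 4))
        group = plant_names[i : i + group_size]
        members: set[str] = set()
        for plant in group:
            members |= truth.plants[plant]
        pathways[f"pathway-{p_idx}"] = members
        i += group_size
        p_idx += 1
    return complexes, pathways
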