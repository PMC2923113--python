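"""Confidence assignment and calibration for detected modules.

The confidence scheme is semi-quantitative thresholding of the module
variables:

* HIGH    — mf_mean, bp_mean and cc_mean all present and >= go_threshold,
* MEDIUM  — bp_mean and cc_mean pass, and cor_mean present and
            >= cor_threshold,
* LOW     — bp_mean and cc_mean pass (but neither of the above holds),
* UNASSIGNED otherwise.

Thresholds are inclusive (>= 0.5 by default).  Calibration ranks modules by
their best FDR-corrected enrichment against gene-set catalogs
(hypergeometric tests, Benjamini–Hochberg within each module); overlap
scores and a cross-talk index characterize each module topologically, and
the mean expression correlation separates permanent from transient modules.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

from scipy import stats
from statsmodels.stats.multitest import multipletests

from .annotate import ModuleVariables
from .netio import InteractionNetwork, Module

HIGH = "HIGH"
MEDIUM = "MEDIUM"
LOW = "LOW"
UNASSIGNED = "UNASSIGNED"

PERMANENT = "PERMANENT"
TRANSIENT = "TRANSIENT"
UNKNOWN = "UNKNOWN"


@dataclass(frozen=True)
class ConfidenceThresholds:
    """Inclusive thresholds for the GO means and the expression correlation."""

    go_threshold: float = 0.5
    cor_threshold: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 <= self.go_threshold <= 1.0 and 0.0 <= self.cor_threshold <= 1.0):
            raise ValueError("thresholds must lie in [0, 1]")


@dataclass(frozen=True)
class EnrichmentResult:
    """One module-vs-gene-set hypergeometric test.

    ``cluster_frequency`` is the (annotated-in-module count, module size)
    pair conventionally printed as e.g. "5/9".
    """

    module_id: str
    set_id: str
    cluster_frequency: tuple[int, int]
    p_value: float
    fdr_q: float


@dataclass(frozen=True)
class OverlapScores:
    jaccard: float
    simpson: float
    geometric: float


def assign_confidence(
    vars: ModuleVariables,
    thresholds: Optional[ConfidenceThresholds] = None,
) -> str:
    """Assign HIGH/MEDIUM/LOW/UNASSIGNED from the module variables.

    A module whose bp/cc means pass but whose cor_mean is absent is LOW (the
    medium criterion cannot be evaluated, so it fails).
    """
    t = thresholds or ConfidenceThresholds()

    def passes(v: Optional[float], cut: float) -> bool:
        return v is not None and v >= cut

    go = t.go_threshold
    if passes(vars.mf_mean, go) and passes(vars.bp_mean, go) and passes(vars.cc_mean, go):
        return HIGH
    if passes(vars.bp_mean, go) and passes(vars.cc_mean, go):
        if passes(vars.cor_mean, t.cor_threshold):
            return MEDIUM
        return LOW
    return UNASSIGNED


def enrich(
    module: Module,
    gene_sets: Mapping[str, Iterable[str]],
    universe: Iterable[str],
) -> list[EnrichmentResult]:
    """Hypergeometric upper-tail enrichment of a module in each gene set.

    Only sets overlapping the module are tested and reported; q-values are
    Benjamini–Hochberg across the sets tested for this module.  Results are
    sorted by ascending p (ties by set id).
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    members = module.members & universe
    if module.members - universe:
        raise ValueError("module members must be contained in the universe")
    big_n = len(universe)
    draw = len(members)
    tested: list[tuple[str, int, float]] = []
    for set_id in sorted(gene_sets):
        in_universe = set(gene_sets[set_id]) & universe
        overlap = len(members & in_universe)
        if overlap == 0:
            continue
        p = float(stats.hypergeom.sf(overlap - 1, big_n, len(in_universe), draw))
        tested.append((set_id, overlap, min(p, 1.0)))
    if not tested:
        return []
    pvals = [p for _, _, p in tested]
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    results = [
        EnrichmentResult(
            module_id=module.module_id,
            set_id=set_id,
            cluster_frequency=(overlap, module.size),
            p_value=p,
            fdr_q=float(q),
        )
        for (set_id, overlap, p), q in zip(tested, qvals)
    ]
    results.sort(key=lambda r: (r.p_value, r.set_id))
    return results


def calibration_rank(
    entries: Sequence[tuple[Module, str, EnrichmentResult]],
) -> list[tuple[Module, str, EnrichmentResult]]:
    """Order modules by their best (minimum q) enrichment; ties by module_id."""
    return sorted(entries, key=lambda e: (e[2].fdr_q, e[0].module_id))


def top_label_composition(
    ranking: Sequence[tuple[Module, str, EnrichmentResult]], k: int
) -> dict[str, int]:
    """Confidence-label composition of the top-k prefix of a calibration rank."""
    return dict(Counter(label for _, label, _ in ranking[:k]))


def overlap_scores(
    module: Module, complexes: Mapping[str, Iterable[str]]
) -> dict[str, OverlapScores]:
    """Jaccard / Simpson / geometric overlap of a module with each complex.

    Complexes with empty intersection are omitted.
    """
    out: dict[str, OverlapScores] = {}
    m = module.members
    for name in sorted(complexes):
        c = set(complexes[name])
        inter = len(m & c)
        if inter == 0 or not c:
            continue
        out[name] = OverlapScores(
            jaccard=inter / len(m | c),
            simpson=inter / min(len(m), len(c)),
            geometric=inter * inter / (len(m) * len(c)),
        )
    return out


def crosstalk_score(module: Module, network: InteractionNetwork) -> float:
    """Fraction of the module's incident degree mass that leaves the module.

    boundary / (boundary + 2 * internal edges); 0 for an isolated clique
    component, 1 for a singleton with external links only.
    """
    g = network.graph
    missing = module.members - network.nodes
    if missing:
        raise ValueError(f"module members not in network: {sorted(missing)[:5]}")
    members = module.members
    internal = 0
    boundary = 0
    for u in members:
        for v in g[u]:
            if v in members:
                internal += 1  # counted from both endpoints
            else:
                boundary += 1
    mass = boundary + internal  # internal already counts each edge twice
    if mass == 0:
        return 0.0
    return boundary / mass


def classify_permanence(
    vars: ModuleVariables, cor_threshold: float = 0.5
) -> str:
    """PERMANENT / TRANSIENT split on mean expression correlation.

    Modules maintained across conditions (complexes such as the proteasome or
    ribosome) show high co-expression; condition-specific assemblies
    (transcription-factor complexes) show low co-expression.
    """
    if vars.cor_mean is None:
        return UNKNOWN
    return PERMANENT if vars.cor_mean >= cor_threshold else TRANSIENT
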