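"""Packaged reference fixtures.

``reference_module_variables`` loads a verbatim table of module annotation
statistics from a published human-interactome modularity study: 24 modules
that passed the confidence thresholds (tiers High / Medium / Low) and 86
residual modules that did not, for both the clique-percolation (CPM) and
MCODE detectors over the literature, orthology, high-throughput and
integrated interactome classes.  The table exercises the confidence rules
exactly as printed (NA marks unavailable GO or correlation means).

The LSM worked example pairs a literature-class module with the LSM1-7
complex: the module's eight members contain all seven complex subunits plus
SMN1, giving per-module precision 7/8 and recall 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Optional

from .annotate import ModuleVariables

#: Members of the literature-class module "Lit-9" (clique percolation).
LSM_MODULE_MEMBERS = frozenset(
    {"LSM1", "LSM2", "LSM3", "LSM4", "LSM5", "LSM6", "LSM7", "SMN1"}
)

#: The LSM1-7 reference complex.
LSM_COMPLEX = frozenset(
    {"LSM1", "LSM2", "LSM3", "LSM4", "LSM5", "LSM6", "LSM7"}
)


@dataclass(frozen=True)
class ReferenceRow:
    """One row of the packaged reference table."""

    method: str  # CPM or MCODE
    tier: str  # High, Medium, Low or Residual
    variables: ModuleVariables


def _parse(value: str) -> Optional[float]:
    return None if value == "NA" else float(value)


def reference_module_variables() -> list[ReferenceRow]:
    """Load the packaged reference table of per-module variables."""
    text = (
        resources.files("ppimodules.data")
        .joinpath("reference_module_variables.tsv")
        .read_text()
    )
    lines = text.strip().split("\n")
    header = lines[0].split("\t")
    expected = [
        "method",
        "tier",
        "module_id",
        "n",
        "n_ex",
        "ex_mean",
        "cor_mean",
        "mf_mean",
        "bp_mean",
        "cc_mean",
    ]
    if header != expected:
        raise ValueError("unexpected reference table header")
    rows = []
    for line in lines[1:]:
        method, tier, module_id, n, n_ex, ex, cor, mf, bp, cc = line.split("\t")
        rows.append(
            ReferenceRow(
                method=method,
                tier=tier,
                variables=ModuleVariables(
                    module_id=module_id,
                    n=int(n),
                    n_ex=int(n_ex),
                    ex_mean=_parse(ex),
                    cor_mean=_parse(cor),
                    mf_mean=_parse(mf),
                    bp_mean=_parse(bp),
                    cc_mean=_parse(cc),
                ),
            )
        )
    return rows
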