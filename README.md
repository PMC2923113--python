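# ppimodules

Module detection, confidence scoring and validation for **protein
interactome classes** — protein–protein interaction networks built from a
single evidence source (literature curation, orthology transfer,
high-throughput screens) or from their union (the integrated interactome).

Densely connected regions of an interactome often correspond to protein
complexes or functional modules, but what a clustering algorithm finds
depends heavily on *which* interactome it is given. This package implements
a multilayer analysis for that question, aimed at systems biologists
comparing evidence sources:

1. **Detection** (`ppimodules.detect`) — four module extractors:
   * *clique percolation* (CPM): a k-clique community is the union of
     k-cliques chained through shared (k−1)-node overlaps; communities may
     overlap;
   * *MCODE*: vertex-weighted core mining (weight = coreness × density of
     the neighborhood's top core) with haircut/fluff post-processing;
   * *greedy modularity maximization*: agglomerative merging that maximizes
     Newman–Girvan modularity
     `Q = Σᵢ [ lᵢ/m − (dᵢ/2m)² ]`
     (lᵢ intra-module edges, dᵢ module degree, m total edges);
   * *walktrap*: Ward-style agglomeration of t-step random-walk distances,
     cut at maximal Q.
2. **Annotation** (`ppimodules.annotate`) — per-module variables: size `n`,
   expressed members `n.ex`, mean expression `ex.mean`, mean pairwise
   Spearman correlation `cor.mean`, and GO co-annotation means `mf.mean`,
   `bp.mean`, `cc.mean`, where the co-annotation of two interacting
   proteins is the Jaccard similarity of their is_a ancestor graphs in one
   GO namespace (namespace root excluded).
3. **Confidence scoring** (`ppimodules.score`) — inclusive 0.5 thresholds:
   HIGH when all three GO means pass; MEDIUM when bp/cc pass and
   `cor.mean ≥ 0.5`; LOW when only bp/cc pass; UNASSIGNED otherwise.
   Plus hypergeometric enrichment with Benjamini–Hochberg FDR, overlap
   scores (Jaccard/Simpson/geometric), a cross-talk index, and a
   permanent/transient split on `cor.mean`.
4. **Validation** (`ppimodules.validate`) — matching frequency against a
   complex catalog (a complex is *well matched* at frequency ≥ 0.5),
   per-module precision/recall `P = tp/(tp+fp)`, `R = tp/(tp+fn)`,
   per-class primed measures `P' = MM/PM`, `R' = MC/KC`, protein-wise
   precision/recall, and discrete power-law fits of module-size
   distributions (MLE exponent, KS-chosen x_min).
5. **Synthetic data** (`ppimodules.synthetic_data`) — a planted-module
   generator producing every pipeline input: class networks sampled from
   one ground truth with class-specific retention/noise, a three-namespace
   ontology with module-coherent annotations, correlated tissue
   expression, and perturbed complex/pathway catalogs.

## Worked example

```python
from ppimodules.datasets import LSM_MODULE_MEMBERS, LSM_COMPLEX
from ppimodules.netio import Module
from ppimodules.validate import module_pr, round_half_away

module = Module("Lit-9", LSM_MODULE_MEMBERS, "CPM", k_param=4, rank_score=8)
counts = module_pr(module, LSM_COMPLEX)
print(round_half_away(counts.precision), counts.recall)
```

prints

```
0.88 1.0
```

The literature-class module contains all seven LSM1–7 subunits plus SMN1,
so 7 of its 8 members are true positives (precision 7/8 → 0.88) and the
complex is fully covered (recall 1).

A full synthetic run from the shell:

```bash
ppimod run --outdir out --seed 1
cat out/validation/class_summary.tsv
```

```
method	class	MM	PM	MC	KC	precision_prime	recall_prime
cpm	LIT	8	8	7.4317	8	1.00	0.93
mcode	LIT	7	10	4.9714	8	0.70	0.62
cpm	ORTHO	7	7	5.6460	7	1.00	0.81
mcode	ORTHO	6	8	3.7492	8	0.75	0.47
cpm	HTP	0	2	0.0000	2	0.00	0.00
mcode	HTP	0	6	0.0000	5	0.00	0.00
cpm	INT	8	8	7.4317	8	1.00	0.93
mcode	INT	5	7	4.1373	8	0.71	0.52
```

Every planted module recovered from the high-coverage literature class
validates against the complex catalog (P′ = 1.00), while the sparse, noisy
high-throughput class recovers almost nothing — the qualitative signature
that disaggregated class quality drives validation performance.

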