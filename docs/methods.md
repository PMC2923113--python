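# Methods

## Problem setting

A protein interactome assembled from one evidence source is called an
*interactome class*: literature-curated interactions (LIT), interactions
transferred by orthology from model organisms (ORTHO), high-throughput
yeast two-hybrid screens (HTP), and their union (INT). Classes differ in
coverage and error structure, and module-extraction algorithms respond
differently to those differences. The package detects modules per class,
attaches annotation-derived confidence labels, and validates the modules
against reference complex catalogs, so that the informativeness of
disaggregated versus integrated classes can be compared quantitatively.

## Detection algorithms

**Clique percolation (CPM).** A k-clique community is the node union of a
maximal set of k-cliques in which consecutive cliques share k−1 nodes.
Communities may overlap in fewer than k−1 nodes; every k-clique belongs to
exactly one community. k = 2 is excluded (pairs joined by single links are
not modules); the default is k = 4, which keeps planted modules separable
when they overlap in at most two proteins. The implementation delegates to
networkx's k-clique-community routine; the test suite checks it against an
independent brute-force enumeration-and-percolation oracle on a corpus of
small random graphs, and checks the nested-resolution property (every
community at k lies inside a community at k−1).

**MCODE.** Each vertex is weighted by the core number of its closed
neighborhood graph times the density of that neighborhood's highest-order
core. Seeds are taken in decreasing weight; breadth-first growth admits
unvisited neighbors with weight ≥ (1 − node_score_cutoff) × seed weight up
to max_depth. The haircut step takes each grown module to its 2-core, so
every surviving member has at least two intra-module neighbors; fluff is
off by default. Defaults: node score cutoff 0.2, haircut on, fluff off,
max depth 100. A module's rank score is intra-module edges per member; its
reported coreness is the minimum intra-module degree. Since the published
algorithm description leaves some operator details open, every free choice
is pinned here (global visited set, deterministic seed order, 2-core
haircut) so runs are reproducible.

**Modularity and greedy maximization.** For a disjoint partition into N
modules with m edges, the mixing matrix entry e_ij is the fraction of edge
mass linking modules i and j (e_ii = l_i/m for intra-module edges; an
inter-module edge contributes 1/2m to each direction), E_i = Σ_j e_ij =
d_i/2m, and

    Q = Tr[E] − Σ_i E_i²  =  Σ_i [ l_i/m − (d_i/2m)² ].

Q is exactly 0 for the single-module partition and approaches 1 for
strongly modular partitions; mixing fractions are accumulated as integer
counts and divided once so the exact limits hold without floating-point
drift. The greedy optimizer starts from singletons and repeatedly merges
the connected pair with the largest ΔQ = e_ij + e_ji − 2 E_i E_j, breaking
ties by the lexicographically smallest pair of community ids (a community's
id is its smallest member), and stops when no merge increases Q.

**Walktrap.** Nodes are compared by their t-step random-walk transition
profiles with degree-normalized components, r²(C₁,C₂) = Σ_k (P^t_{C₁k} −
P^t_{C₂k})²/d_k, communities merged by Ward's criterion (adjacent pairs
only), and the partition along the merge tree with maximal Q is returned.
Default t = 4. Each connected component is agglomerated independently;
because Q decomposes over communities, per-component cuts maximize the
global Q.

On small clique-modular graphs (clique blocks joined by sparse bridges)
both agglomerative methods attain the exhaustive-search Q optimum, and the
tests assert this; on modularity-weak graphs such as long cycles and paths
the heuristics can stop below the optimum, which is inherent to
agglomerative merging, not an implementation artifact.

**Community selection.** The two-step reduction of k-clique communities:
forward, for each k ≥ 4, communities larger than 200 members are dropped
and at most five communities closest to the median size for that k are
kept; backward, from the largest k down, a community is kept only if its
member set is not contained in an already selected community.

## Annotation variables

For each module: n (size), n.ex (members present in the expression
matrix), ex.mean (pooled mean over all cells of the expressed members'
rows — the pooled convention is a deliberate choice where per-protein
averaging would also have been defensible), cor.mean (mean pairwise
Spearman correlation, midranks for ties, over all unordered pairs of
expressed members; pairs with zero rank variance are dropped; absent when
n.ex < 2), and one co-annotation mean per GO namespace.

Co-annotation of two proteins is |A∩B|/|A∪B| over their ancestor graphs:
the is_a closure of their assigned terms in one namespace, with the
namespace root excluded — the root is shared by every annotated protein
and would put a floor under every similarity. Only is_a edges are
traversed. GO means average over intra-module *interacting* pairs (network
edges), because co-annotation is a property of interacting proteins;
cor.mean averages over all expressed-member pairs. Pairs with an empty
ancestor graph are dropped from the mean rather than scored 0. Node-set
Jaccard is used; in a fixed DAG the edge set of an ancestor closure is
determined by its node set, so a node-and-edge variant would rank pairs
identically.

## Confidence scheme

Thresholds are inclusive (≥), default 0.5 for both the GO means and the
correlation. HIGH requires all three GO means; MEDIUM requires bp and cc
plus a measured cor.mean ≥ 0.5; LOW requires bp and cc only; everything
else is UNASSIGNED. A module whose bp/cc pass but whose cor.mean is
unmeasurable is LOW: the medium criterion cannot be evaluated, so it is
not granted. The labels form mutually exclusive tiers (a module meeting
the HIGH rule is never also MEDIUM). The packaged reference table of 110
modules exercises every branch, including a LOW row with bp exactly 0.5
that forces the inclusive comparison.

Calibration ranks modules by their best Benjamini–Hochberg-corrected
hypergeometric enrichment across a gene-set catalog (BH within each module
over the sets actually tested, i.e. those with nonzero overlap). Overlap
against complexes is summarized by the standard triple Jaccard
|M∩C|/|M∪C|, Simpson |M∩C|/min(|M|,|C|) and geometric |M∩C|²/(|M|·|C|);
the triple is a package choice where several overlap indices would serve,
and is replaceable. The cross-talk index of a module is
boundary/(boundary + 2·internal): the fraction of incident degree mass
leaving the module (0 for an isolated clique, 1 for a singleton with only
external links). Permanence: PERMANENT when cor.mean ≥ 0.5, TRANSIENT when
below, UNKNOWN when unmeasured; the 0.5 default reuses the medium/low
split since only a qualitative high/low distinction is available.

## Validation

Matching frequency of module M against complex C is |M∩C|/|C|; C is well
matched at ≥ 0.5. Per-module tp/fp/fn are member-set counts against one
complex. Per class: each module is assigned its best-frequency complex
(ties broken by larger intersection, then name); MM counts modules with
best frequency ≥ 0.5, PM is the module count, KC counts complexes detected
with nonzero frequency (the detected-complex convention; a whole-catalog
variant is a one-line change at the call site), and MC sums each module's
mean qualifying frequency; P′ = MM/PM, R′ = MC/KC. A class that yields no
modules is assigned P′ = 0 by convention in class-level comparisons.
Printed-value comparison rounds half away from zero to two decimals
(0.875 → 0.88).

Module-size distributions are fitted with the discrete power-law recipe:
for each candidate x_min (with at least 10 tail observations), the MLE
exponent maximizes −n·ln ζ(α, x_min) − α·Σ ln x via bounded scalar
optimization (α ∈ (1, 10]), and x_min minimizes the KS distance between
the empirical and fitted tail survival functions. The exact sampler used
in tests draws Zipf variates and conditions on x ≥ x_min, which preserves
the power-law form.

## Synthetic data: what it emulates and what it does not

The generator plants n_plants dense modules (default 8, sizes 6–12,
internal density 0.9) over a 300-node background of density 0.005, drawn
pairwise disjoint — within the at-most-two-protein overlap budget that
keeps CPM at k = 4 separable. Classes keep each true edge independently
(LIT 0.9, ORTHO 0.7, HTP 0.4) and add spurious non-edges at 2% / 5% / 15%
of the kept count; the rates are a package choice making the
high-throughput class noisiest and sparsest, mirroring the relative
quality of real evidence sources. INT is the edge union. Annotations give
each plant a home leaf per namespace in a random 3-ary is_a tree of depth
4; members receive the home leaf with probability 0.9, a random leaf with
probability 0.05, nothing otherwise; background proteins get uniform
leaves. Expression mixes a per-plant latent profile with noise,
√ρ·latent + √(1−ρ)·noise + 8, with ρ = 0.8 for permanent and 0.1 for
transient plants over 50 tissues; the baseline of 8 with unit noise puts
ex.mean in the 8–12 range typical of log-scale expression atlases
(cosmetic only). Complex catalogs are plants with 10% member dropout and
10% contamination; pathways are unions of 1–3 plants.

Not emulated: study bias toward well-known hub proteins, correlated
(non-independent) evidence between classes, curation error modes,
evidence-code structure in annotations, and tissue–tissue correlation in
expression. Passing tests therefore demonstrate that the pipeline's
machinery recovers planted structure under the stated noise model, not
that any particular real interactome has that structure.

## Problem sizes and numerical choices

The default synthetic study (about 370 proteins, hundreds of edges per
class) runs the full pipeline in a few seconds; the oracle comparisons use
exhaustive enumeration on graphs of up to 10 nodes and exhaustive
partition search up to 8 nodes, and the power-law recovery uses 10⁴
samples over 20 replicates — sizes chosen so every check is exact or
well-powered while the suite stays quick. Tolerances: modularity identities
are exact (integer accumulation); agreement checks use absolute 1e-12;
stochastic recovery rates are asserted against the thresholds stated above
at fixed seeds. Degenerate inputs are errors, not silent defaults:
edgeless networks for modularity-based detectors, empty complexes or
catalogs, all-equal size samples for the power-law fit.

## Known limitations

* The agglomerative detectors are heuristics; optimality is guaranteed
  only on the curated clique-modular test graphs.
* CPM uses exact clique enumeration, appropriate for desk-scale networks,
  not for interactomes with tens of thousands of proteins.
* Per-class P′/R′ are unstable when a class yields very few modules (a
  single lucky module gives P′ = 1); comparisons should be read with the
  module counts alongside.
* The confidence scheme is semi-quantitative thresholding by design; no
  weighting or learning across evidence channels is attempted.
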