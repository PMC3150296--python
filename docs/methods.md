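# Methods

## The model

An ontology is a rooted DAG G = (T, E) whose edges are *is-a* relations
from child (more specific) to parent (more general). An annotation corpus
assigns each gene a set of direct terms; annotations propagate upward, so
the annotation probability of a term is

p(t) = |genes annotated to t or any descendant| / |annotated genes|,

counting distinct genes, and IC(t) = −log p(t). The root has p = 1,
IC = 0; p is non-increasing and IC non-decreasing from parent to child.
The denominator is the *annotated* universe, not a genome-wide gene count:
that keeps M ≤ N in the enrichment model and makes p(root) exactly 1. A
genome-wide N can still be supplied explicitly to `enrich` for replication
against externally defined universes.

The logarithm is natural by default and configurable. The base cancels in
every ratio measure (Lin, Rel, GIC, simIC, CoutoLin — tested explicitly)
but rescales Resnik/CoutoResnik and shifts where the Jiang–Conrath clamp
1 − min(1, distance) saturates, so the base is recorded in all written
metadata.

## Shared information: MICA and GraSM

The MICA of two terms is their common ancestor of maximal IC (ties break
to the lexicographically smallest accession; tie order cannot affect any
reported value because tied ancestors have equal IC). GraSM refines this:
two ancestors a₁, a₂ of t are *disjunctive* when each reaches t by a
directed path avoiding the other; a common ancestor a of (t₁, t₂) is a
*disjunctive common ancestor* iff for every common ancestor a′ with
IC(a′) strictly greater than IC(a), the pair (a, a′) is disjunctive for
t₁ or for t₂. The strictly-greater comparison means equal-IC ancestors
never exclude one another; Share(t₁,t₂) is the mean IC over the DCA set,
and on any tree-shaped ancestor structure the DCA set collapses to the
MICA, making the Couto variants coincide exactly with Resnik/Lin/JC
(property-tested to 1e−12). Path-avoidance treats endpoints as "passed
through", so no pair involving t itself is disjunctive and DCA(t,t)={t}.
The implementation (reachability in the DAG with one node removed) is
checked against exhaustive all-simple-paths enumeration on hundreds of
random DAGs of ≤ 12 terms — small enough for full enumeration, large
enough to contain multi-parent diamonds.

## The Wang measure

Edge weight w_e ∈ (0,1), default 0.7 — the conventional value for *is-a*
edges and the only edge type supported. Contributions are computed by
dynamic programming over a topological order of the ancestor sub-DAG; the
contract (result equals the maximum over all paths of the edge-weight
product) is tested against brute-force path enumeration. Wang never reads
the corpus, so terms with zero annotation count remain scorable and the
values are invariant under corpus permutation.

## Degenerate inputs and conventions

- Both terms the root: ratio measures resolve 0/0 to 1 (Lin, GIC,
  CoutoLin); Rel and simIC then multiply by factors that are 0 at the
  root, which is the correct limit (the root carries no information).
- Terms with p = 0 are absent from the IC table and raise a domain error
  naming the term in IC-based measures.
- Resnik is reported unnormalized (the diagonal of a Resnik matrix is each
  term's own IC); gene matrices record measure/method in `DataFrame.attrs`
  and in the TSV metadata header.
- Multi-root OBO files get a synthetic root `SYN:0000000` inserted above
  all parentless terms so a common ancestor always exists; it is never
  annotated directly but acquires p = 1 by propagation, hence IC = 0 — it
  is IC-neutral. Obsolete terms are retained for lookup but excluded from
  edges and every computation; non-*is-a* relationship lines are dropped
  with a warning; `alt_id` accessions resolve to their canonical term.

## Gene similarity

A gene's term set is its *direct* annotations, not the propagated closure
— propagation would inflate shallow shared ancestry that the measures
already account for. Genes with no annotations are dropped from matrix
construction with a logged report rather than scored zero. Diagonals are
computed, not forced: all best-match methods give 1 on normalized
measures but meaningful self-IC values under Resnik. The orderings
Mean ≤ funSimAvg ≤ funSimMax ≤ Max and Mean ≤ BMA ≤ Max follow from the
row/column-maxima definitions and are property-tested on thousands of
random matrices.

## Enrichment

Candidates are terms with propagated count ≥ *filter* and depth ≥ *layer*
(depth = shortest root path, root 0; "deeper = more specific", so the
layer criterion excludes overly general terms). The p-value is the exact
hypergeometric upper tail (scipy's survival function, evaluated stably in
log space internally), verified against full k-subset enumeration at
small N. BH-FDR is applied *after* the filter/layer restriction: the
criteria are a pre-specified candidate definition, not a data-driven
selection, so the multiple-testing family is the candidate set. Raising
either criterion never adds candidates (anti-monotone selection, tested).

## Module detection

Similarity matrices are converted to distances d = 1 − s (after rescaling
by the matrix maximum when values exceed 1, i.e. for unnormalized
measures), with a forced zero diagonal. Clustering is UPGMA via
scipy. Two cuts are provided:

- **Static**: connected components of merges strictly below a height;
  components smaller than `min_size` stay unassigned (module 0).
  Cuts at increasing heights are nested (tested).
- **Dynamic ("tree" variant)**: recursive top-down splitting. Within a
  branch, the largest gap between consecutive sorted merge heights is
  located; if it exceeds `gap_frac` (default 0.3) times the full
  dendrogram height, the branch is cut in the middle of that gap and the
  sub-branches are revisited; otherwise the branch is accepted as a
  module when it has ≥ `min_size` leaves. Every module is therefore a
  contiguous dendrogram branch (structurally tested). The gap threshold
  is relative to the *global* tree height so that noise-scale gaps inside
  tight clusters never trigger spurious splits. `min_size` is the only
  exposed knob; `gap_frac` is a numerical constant of the method.

Module significance: observed mean off-diagonal within-module similarity
versus random same-size subsets of the matrix labels, p = (b+1)/(reps+1)
with add-one smoothing so p never reaches 0 at finite reps (the floor is
1/(reps+1)); FDR across modules by BH. The permutation threshold utility
pools all pairwise similarities across repeated random subsets and
returns a percentile — the machinery behind "significant pair" network
exports. All draws come from one `numpy.random.default_rng(seed)`.

## Synthetic data

The generators define the test conditions:

- `fixture_toy9`: nine terms (root, two branches, one multi-parent
  diamond, two leaves, two obsolete padding terms) and eight genes each
  annotated to one or two terms — the smallest structure exhibiting every
  interesting case (containment, diamond, disjunctive ancestors), fully
  hand-checkable. Its `expected` table is re-derived in-file from the
  count arithmetic, and tests additionally confirm each value against
  brute-force oracles.
- `random_ontology`: layered DAGs (terms spread over depths 1..target,
  parents drawn from strictly shallower layers — acyclic by
  construction). `max_parents=1` yields trees for the reduction tests.
- `random_corpus`: uniform annotation draws, root excluded; optional
  per-leaf sentinel genes guarantee p(t) > 0 everywhere.
- `planted_similarity`: block matrices (within 0.9, between 0.1, Gaussian
  noise sd 0.02, clipped and symmetrized) with ground-truth labels for
  recovery tests.

What these emulate: the topology and annotation sparsity of real
*is-a* ontologies at miniature scale. What they do not: realistic term
counts (thousands), scale-free fan-out, correlated annotations, or the
biases of curated corpora — so passing tests demonstrate correctness of
the computations, not biological performance of any measure on real data.

## Problem sizes

Tests and the acceptance script run at deliberately small scale: DAGs of
5–50 terms, corpora of ≤ 40 genes, 200 random DAGs for the enumeration
equivalence, 1000 random matrices for the aggregation ordering, 20
planted-partition seeds, permutation reps in the hundreds to a few
thousand. These sizes make exhaustive oracles exact and keep the whole
suite under a few seconds while exercising every code path.

## Known limitations

- Only *is-a* semantics; part-of/regulates ontologies are out of scope.
- The dynamic cut implements the adaptive tree variant only, not the
  hybrid variant that re-assigns singletons by medoid distance.
- Hierarchical-clustering tie-breaking follows scipy's deterministic
  nearest-neighbor-chain order; for matrices with exactly tied distances
  the merge order (not the merge heights) may differ from other UPGMA
  implementations.
- GO/KEGG-style multilayered annotation of modules is supported only
  mechanically (via the flat-map enrichment engine); no annotation data
  is bundled.
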