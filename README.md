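# ontosim

Semantic similarity over *is-a* ontologies, for researchers who want to
quantify how related two controlled-vocabulary terms are — and, through
annotations, how related two genes are in terms of those concepts. The
motivating instance is the Disease Ontology (DO): diseases form a rooted
directed acyclic graph of subtype (*is-a*) relations, genes carry disease
annotations, and "how similar are these two diseases / these two genes?"
becomes a graph-and-information-theory question. The toolkit is generic:
any OBO 1.2 ontology restricted to *is-a* edges plus a two-column
gene-to-term annotation table works.

## What it computes

**Term–term similarity (ten measures).** With p(t) the fraction of the
annotated gene universe annotated to term *t* or any descendant,
IC(t) = −log p(t) measures specificity. Writing I₁, I₂ for the ICs of two
terms, I_M for the IC of their most-informative common ancestor (MICA),
and Sh for the GraSM shared information (the mean IC over the disjunctive
common ancestors — ancestors that each reach the term by a path avoiding
the other):

- Resnik = I_M;  Lin = 2·I_M/(I₁+I₂);  JC = 1 − min(1, I₁+I₂−2·I_M)
- Rel = Lin·(1−p(MICA));  simIC = Lin·(1 − 1/(1+I_M))
- GIC = Σ IC(common ancestors) / Σ IC(ancestor union)
- CoutoResnik = Sh;  CoutoLin = 2·Sh/(I₁+I₂);  CoutoJC = 1 − min(1, I₁+I₂−2·Sh)
- Wang: structure-only; each ancestor *a* of *t* contributes the maximal
  product of edge weights w_e (default 0.7) along a path *a* → *t*, and
  Wang(A,B) = Σ_{a∈shared} (S_A(a)+S_B(a)) / (SV(A)+SV(B)).

**Gene–gene similarity (five aggregations).** A gene is its set of direct
annotations; the m×n matrix S of term-pair similarities between two genes'
sets is condensed by Max, Mean, funSimMax, funSimAvg, or the best-match
average BMA = (Σ row maxima + Σ column maxima)/(m+n) — fifty measure×method
combinations in total.

**Enrichment.** Upper-tail hypergeometric test per term with *filter*
(minimum propagated annotation count) and *layer* (minimum DAG depth)
candidate criteria and Benjamini–Hochberg FDR; also runs on flat
term→gene maps with no ontology.

**Module detection.** Similarity → distance (d = 1 − s), average-linkage
hierarchical clustering, then either a constant-height cut or an adaptive
"tree" branch cut; module significance by permutation of same-size label
subsets, with add-one-smoothed p-values and a permutation-percentile
significance threshold for pairwise similarities.

**Ontology utilities.** OBO parsing and validation, ancestors /
descendants / depth / sibling queries, induced ancestor subgraphs, and
GraphML / DOT / edge-list / Newick exports.

## Worked example

```sh
python examples/term_similarity.py
```

prints, for the built-in nine-term fixture (two leaves E and F whose only
informative shared ancestor A has IC 0.2877 nats):

```
pair: TOY:0000005 (leaf E) vs TOY:0000006 (leaf F)
IC(E) = 1.3863 nats, IC(F) = 1.3863 nats
  resnik       0.2877
  lin          0.2075
  jc           0.0000
  rel          0.0519
  gic          0.0503
  simic        0.0464
  coutoresnik  0.1438
  coutolin     0.1038
  coutojc      0.0000
  wang         0.2999
```

Resnik reports the MICA's IC itself; Lin rescales it by the terms' own
ICs; the Couto variants replace the MICA's IC with the mean over the
disjunctive common ancestors {A, root} (0.1438), which discounts the pair
for meeting through two independent routes; Wang ignores the corpus
entirely and scores shared ancestry by best-path edge-weight products.
The other scripts in `examples/` walk gene similarity, enrichment, module
detection, and ontology queries the same way, and the `ontosim` command
line (`ontosim termsim|genesim|enrich|modules|graph --help`) exposes the
same operations on files.

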