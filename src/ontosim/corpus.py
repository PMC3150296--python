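"""Annotation corpora and information content.

A corpus maps genes to the ontology terms they are directly annotated with.
Annotations propagate upward (a gene annotated to a term is implicitly
annotated to every ancestor), giving each term an annotation probability

    p(t) = (# distinct genes annotated to t or any descendant) / (# annotated genes)

and an information content IC(t) = -log p(t).  The root has p = 1 and IC = 0;
terms never touched by the corpus have p = 0 and no defined IC, which removes
them from the domain of the IC-based similarity measures (the structure-only
Wang measure still covers them).
"""

from __future__ import annotations

import io
import logging
import math
from dataclasses import dataclass, field

import pandas as pd

from .ontology import OntologyDAG

logger = logging.getLogger(__name__)


class AnnotationParseError(ValueError):
    pass


@dataclass
class AnnotationCorpus:
    """Direct gene → term annotations over a companion DAG."""

    direct: dict[str, set[str]] = field(default_factory=dict)

    @property
    def universe_size(self) -> int:
        return len(self.direct)

    @property
    def genes(self) -> list[str]:
        return list(self.direct)

    def terms_of(self, gene: str) -> set[str]:
        """Direct annotation set of one gene (empty if unknown)."""
        return set(self.direct.get(gene, set()))

    def to_tsv(self) -> str:
        lines = ["#gene\tterm"]
        for g in sorted(self.direct):
            for t in sorted(self.direct[g]):
                lines.append(f"{g}\t{t}")
        return "\n".join(lines) + "\n"


def load_annotations(source, dag: OntologyDAG) -> AnnotationCorpus:
    """Read a two-column (gene, term accession) TSV into a corpus.

    Comment lines start with ``#``.  Rows naming unknown or obsolete
    accessions are dropped and counted in a logged summary; duplicate rows
    collapse.  alt_id accessions resolve to their canonical term.
    """
    if isinstance(source, str) and ("\n" in source or "\t" in source):
        source = io.StringIO(source)
    if isinstance(source, str):
        source = open(source)
    direct: dict[str, set[str]] = {}
    dropped = 0
    with source:
        for lineno, raw in enumerate(source, 1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise AnnotationParseError(
                    f"line {lineno}: expected 2 tab-separated columns, got {len(fields)}")
            gene, acc = fields[0].strip(), dag.resolve(fields[1].strip())
            if acc not in dag.terms or dag.terms[acc].obsolete:
                dropped += 1
                continue
            direct.setdefault(gene, set()).add(acc)
    if dropped:
        logger.info("dropped %d annotation rows with unknown/obsolete accessions", dropped)
    return AnnotationCorpus(direct)


def propagated_counts(dag: OntologyDAG, corpus: AnnotationCorpus) -> dict[str, int]:
    """Distinct-gene count per term after upward propagation.

    count(t) = |union over t and its descendants of the direct gene sets|.
    A gene annotated to several descendants of t counts once.
    """
    gene_sets = propagated_genes(dag, corpus)
    return {t: len(gs) for t, gs in gene_sets.items()}


def propagated_genes(dag: OntologyDAG, corpus: AnnotationCorpus) -> dict[str, set[str]]:
    """Per-term set of genes annotated to the term or any descendant."""
    direct_by_term: dict[str, set[str]] = {t: set() for t in dag.live_terms()}
    for gene, terms in corpus.direct.items():
        for t in terms:
            direct_by_term.setdefault(t, set()).add(gene)
    out: dict[str, set[str]] = {}
    # accumulate children into parents in reverse topological order
    import networkx as nx
    for t in nx.topological_sort(dag.graph):  # children before parents
        gs = set(direct_by_term.get(t, ()))
        for child in dag.graph.predecessors(t):
            gs |= out[child]
        out[t] = gs
    return out


@dataclass
class ICTable:
    """Per-term annotation probability and information content.

    ``ic`` only holds terms with p > 0; ``log_base`` records the logarithm
    used (natural by default — the base cancels in every ratio measure but
    changes the absolute Resnik/JC scale).
    """

    p: dict[str, float]
    ic: dict[str, float]
    log_base: float
    universe_size: int

    def domain(self) -> set[str]:
        """Terms with a defined IC."""
        return set(self.ic)

    def __contains__(self, t: str) -> bool:
        return t in self.ic

    def to_frame(self) -> pd.DataFrame:
        rows = [(t, self.p[t], self.ic.get(t)) for t in sorted(self.p)]
        return pd.DataFrame(rows, columns=["accession", "p", "ic"])

    def to_tsv(self) -> str:
        head = (f"#universe_size={self.universe_size}\n"
                f"#log_base={'e' if self.log_base == math.e else self.log_base}\n")
        return head + self.to_frame().to_csv(sep="\t", index=False)


def information_content(dag: OntologyDAG, corpus: AnnotationCorpus,
                        log_base: float = math.e) -> ICTable:
    """Compute p(t) and IC(t) from propagated annotation counts."""
    if corpus.universe_size == 0:
        raise ValueError("cannot compute information content on an empty corpus")
    if log_base <= 0 or log_base == 1:
        raise ValueError(f"invalid log base {log_base}")
    counts = propagated_counts(dag, corpus)
    n = corpus.universe_size
    p = {t: c / n for t, c in counts.items()}
    ic = {t: -math.log(pt) / math.log(log_base) for t, pt in p.items() if pt > 0}
    return ICTable(p=p, ic=ic, log_base=log_base, universe_size=n)
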