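"""Hypergeometric term enrichment with filter/layer selection and BH-FDR.

Given a query gene set of size k drawn from an annotated universe of N
genes, a term with M propagated annotations and x of the query genes among
them is scored by the upper-tail hypergeometric probability

    p = sum_{i=x}^{min(M,k)} C(M,i) C(N-M,k-i) / C(N,k).

Candidate terms must carry at least ``filter`` propagated annotations and
sit at depth >= ``layer`` in the DAG (depth of the root is 0) — the layer
criterion screens out overly general terms.  FDR control is
Benjamini–Hochberg across the candidate set only.

The same engine runs on a flat term → gene map with no ontology (the depth
criterion is then skipped), which is how arbitrary annotation vocabularies
plug into module annotation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .corpus import AnnotationCorpus, propagated_genes
from .ontology import OntologyDAG

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EnrichmentConfig:
    """Candidate-term criteria: minimum propagated count and minimum depth."""

    filter: int = 5
    layer: int = 0
    alpha: float = 1.0

    def __post_init__(self):
        if self.filter < 1:
            raise ValueError("filter must be >= 1")
        if self.layer < 0:
            raise ValueError("layer must be >= 0")


@dataclass
class EnrichmentRecord:
    term: str
    name: str
    depth: int
    x: int
    M: int
    k: int
    N: int
    p_value: float
    fdr: float = float("nan")
    genes: tuple[str, ...] = field(default_factory=tuple)


def hypergeom_pvalue(N: int, M: int, k: int, x: int) -> float:
    """Upper-tail hypergeometric mass P(X >= x)."""
    if not (0 <= M <= N and 0 <= k <= N and 0 <= x <= min(M, k)):
        raise ValueError(f"invalid hypergeometric bounds N={N} M={M} k={k} x={x}")
    # sf(x-1) = P(X >= x); scipy evaluates the tail stably in log space
    return float(min(1.0, hypergeom.sf(x - 1, N, M, k)))


def bh_fdr(p_values) -> list[float]:
    """Benjamini–Hochberg step-up adjusted values, in input order."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return []
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return list(multipletests(p, method="fdr_bh")[1])


def enrich(dag: OntologyDAG, corpus: AnnotationCorpus, gene_set,
           config: EnrichmentConfig = EnrichmentConfig(),
           universe_size: int | None = None) -> list[EnrichmentRecord]:
    """Term enrichment of a gene set against a propagated corpus.

    ``universe_size`` overrides N (e.g. with a genome-wide count) for strict
    replication; by default N is the annotated-universe size, which
    guarantees M <= N.  Query genes absent from the universe are dropped
    from k with a log message.  Records come back sorted by p ascending.
    """
    gene_set = list(dict.fromkeys(gene_set))
    if not gene_set:
        raise ValueError("empty gene set")
    universe = set(corpus.direct)
    query = [g for g in gene_set if g in universe]
    if not query:
        raise RuntimeError("no gene overlaps the annotation universe")
    if len(query) < len(gene_set):
        logger.info("dropped %d query genes outside the universe",
                    len(gene_set) - len(query))
    by_term = propagated_genes(dag, corpus)
    N = corpus.universe_size if universe_size is None else universe_size
    k = len(query)
    qset = set(query)
    records = []
    for t, genes in by_term.items():
        M = len(genes)
        if M < config.filter or dag.depth(t) < config.layer:
            continue
        hits = sorted(qset & genes)
        records.append(EnrichmentRecord(
            term=t, name=dag.terms[t].name, depth=dag.depth(t),
            x=len(hits), M=M, k=k, N=N,
            p_value=hypergeom_pvalue(N, M, k, len(hits)),
            genes=tuple(hits)))
    _attach_fdr_and_sort(records)
    return records


def enrich_flat(term_to_genes: dict[str, set[str]], gene_set, min_count: int = 1,
                universe: set[str] | None = None) -> list[EnrichmentRecord]:
    """Enrichment over a flat term → gene map (no DAG, no depth criterion)."""
    gene_set = list(dict.fromkeys(gene_set))
    if not gene_set:
        raise ValueError("empty gene set")
    if universe is None:
        universe = set().union(*term_to_genes.values()) if term_to_genes else set()
    query = set(gene_set) & universe
    if not query:
        raise RuntimeError("no gene overlaps the annotation universe")
    N, k = len(universe), len(query)
    records = []
    for t, genes in term_to_genes.items():
        genes = genes & universe
        if len(genes) < min_count:
            continue
        hits = sorted(query & genes)
        records.append(EnrichmentRecord(
            term=t, name=t, depth=0, x=len(hits), M=len(genes), k=k, N=N,
            p_value=hypergeom_pvalue(N, len(genes), k, len(hits)), genes=tuple(hits)))
    _attach_fdr_and_sort(records)
    return records


def _attach_fdr_and_sort(records: list[EnrichmentRecord]) -> None:
    fdrs = bh_fdr([r.p_value for r in records])
    for r, q in zip(records, fdrs):
        r.fdr = q
    records.sort(key=lambda r: (r.p_value, r.term))


def records_to_frame(records: list[EnrichmentRecord]) -> pd.DataFrame:
    rows = [(r.term, r.name, r.depth, r.x, r.M, r.k, r.N, r.p_value, r.fdr,
             ";".join(r.genes)) for r in records]
    return pd.DataFrame(rows, columns=["term", "name", "depth", "x", "M", "k",
                                       "N", "p_value", "fdr", "genes"])
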