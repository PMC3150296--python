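"""Gene–gene similarity by aggregation of term–term similarities.

A gene is represented by its set of *direct* term annotations.  For genes
g1, g2 with term sets of sizes m and n, the pairwise term similarities form
an m x n matrix S; five aggregation methods condense S into one number:

    Max        = max S
    Mean       = grand mean of S
    funSimMax  = max(rowScore, columnScore)
    funSimAvg  = (rowScore + columnScore) / 2
    BMA        = (sum of row maxima + sum of column maxima) / (m + n)

where rowScore / columnScore are the means of the row / column maxima.
Combined with the ten term measures this yields fifty gene similarity
variants.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .corpus import AnnotationCorpus, ICTable
from .ontology import OntologyDAG
from .termsim import DEFAULT_WE, term_similarity

logger = logging.getLogger(__name__)

METHODS = ("max", "mean", "funsimmax", "funsimavg", "bma")


class UnannotatedGeneError(ValueError):
    pass


def term_set_similarity(s: np.ndarray, method: str = "bma") -> float:
    """Aggregate an m x n term-pair similarity matrix into one score."""
    method = method.lower()
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
    s = np.asarray(s, dtype=float)
    if s.ndim != 2 or s.size == 0:
        raise ValueError("similarity matrix must be non-empty and 2-D")
    if not np.isfinite(s).all():
        raise ValueError("similarity matrix contains non-finite values")
    row_max = s.max(axis=1)
    col_max = s.max(axis=0)
    if method == "max":
        return float(s.max())
    if method == "mean":
        return float(s.mean())
    if method == "funsimmax":
        return float(max(row_max.mean(), col_max.mean()))
    if method == "funsimavg":
        return float((row_max.mean() + col_max.mean()) / 2)
    m, n = s.shape
    return float((row_max.sum() + col_max.sum()) / (m + n))  # bma


def _pair_matrix(dag: OntologyDAG, ic: ICTable | None, terms1, terms2,
                 measure: str, w_e: float) -> np.ndarray:
    return np.array([[term_similarity(dag, ic, a, b, measure, w_e) for b in terms2]
                     for a in terms1])


def gene_similarity(dag: OntologyDAG, ic: ICTable | None, corpus: AnnotationCorpus,
                    g1: str, g2: str, measure: str = "lin", method: str = "bma",
                    w_e: float = DEFAULT_WE) -> float:
    """Similarity of two genes from their direct annotation sets."""
    terms1 = sorted(corpus.terms_of(g1))
    terms2 = sorted(corpus.terms_of(g2))
    for g, ts in ((g1, terms1), (g2, terms2)):
        if not ts:
            raise UnannotatedGeneError(f"gene {g!r} has no annotations")
    s = _pair_matrix(dag, ic, terms1, terms2, measure, w_e)
    return term_set_similarity(s, method)


def gene_similarity_matrix(dag: OntologyDAG, ic: ICTable | None, corpus: AnnotationCorpus,
                           genes: list[str], measure: str = "lin", method: str = "bma",
                           w_e: float = DEFAULT_WE) -> pd.DataFrame:
    """Symmetric gene similarity matrix; unannotated genes are dropped.

    The diagonal is computed, not forced to 1, so unnormalized measures
    (Resnik, CoutoResnik) keep a meaningful self-similarity scale.
    """
    if len(set(genes)) != len(genes):
        raise ValueError("duplicate genes in list")
    kept = [g for g in genes if corpus.terms_of(g)]
    dropped = [g for g in genes if g not in set(kept)]
    if dropped:
        logger.info("dropped %d unannotated genes: %s", len(dropped), dropped)
    if len(kept) < 2:
        raise ValueError(f"fewer than two annotated genes remain (kept {len(kept)})")
    n = len(kept)
    vals = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            vals[i, j] = vals[j, i] = gene_similarity(
                dag, ic, corpus, kept[i], kept[j], measure, method, w_e)
    df = pd.DataFrame(vals, index=kept, columns=kept)
    df.attrs.update(measure=measure, method=method, dropped=dropped)
    return df
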