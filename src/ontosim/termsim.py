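"""Term–term semantic similarity: ten measures over an is-a DAG.

Nine measures are information-content based.  With I1 = IC(t1), I2 = IC(t2),
IM = IC of the most-informative common ancestor (MICA) and Sh the GraSM
shared information (mean IC over the disjunctive common ancestors, DCA):

    Resnik       = IM
    Lin          = 2 IM / (I1 + I2)
    JC           = 1 - min(1, I1 + I2 - 2 IM)        (Jiang–Conrath, as similarity)
    Rel          = Lin * (1 - p(MICA))               (relevance)
    GIC          = sum IC(common ancestors) / sum IC(ancestor union)
    simIC        = Lin * (1 - 1 / (1 + IM))
    CoutoResnik  = Sh
    CoutoLin     = 2 Sh / (I1 + I2)
    CoutoJC      = 1 - min(1, I1 + I2 - 2 Sh)

The tenth, the Wang measure, is structure-only: each ancestor a of a term t
contributes the maximal product of edge weights w_e along a path a -> t
(contribution of t to itself is 1); SV(t) is the sum of contributions, and

    Wang(t1, t2) = sum over shared ancestors of (S_t1(a) + S_t2(a)) / (SV(t1) + SV(t2)).

Ancestor sets include the term itself throughout.  When both terms are the
root (I1 + I2 = 0) the ratio measures resolve the 0/0 to 1.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .corpus import ICTable
from .ontology import OntologyDAG

MEASURES = ("resnik", "lin", "jc", "rel", "gic", "simic",
            "coutoresnik", "coutolin", "coutojc", "wang")

#: measures whose values live in [0, 1]
NORMALIZED_MEASURES = frozenset(m for m in MEASURES if m not in ("resnik", "coutoresnik"))

#: default semantic contribution factor of an is-a edge in the Wang measure
DEFAULT_WE = 0.7


class MeasureDomainError(ValueError):
    """A term lacks the information content an IC-based measure requires."""


@dataclass(frozen=True)
class TermPairShared:
    """Shared-information summary of a term pair: MICA and GraSM DCA set."""

    mica: str
    mica_ic: float
    dca: frozenset[str]
    share: float


@dataclass(frozen=True)
class SemanticContributionMap:
    """Wang semantic contributions of a term's ancestor sub-DAG."""

    target: str
    contributions: dict[str, float] = field(hash=False)
    w_e: float = DEFAULT_WE

    @property
    def sv(self) -> float:
        return sum(self.contributions.values())


def _ic_check(ic: ICTable, *terms: str) -> None:
    for t in terms:
        if t not in ic:
            raise MeasureDomainError(
                f"term {t!r} has no information content (zero annotation count)")


def mica(dag: OntologyDAG, ic: ICTable, t1: str, t2: str) -> tuple[str, float]:
    """Most informative common ancestor and its IC.

    Ties on IC break toward the lexicographically smallest accession.
    """
    t1, t2 = dag._check(t1), dag._check(t2)
    _ic_check(ic, t1, t2)
    common = dag.ancestors(t1) & dag.ancestors(t2) & ic.domain()
    if not common:
        raise RuntimeError(f"no common ancestor with defined IC for {t1!r}, {t2!r}")
    best = min(common, key=lambda a: (-ic.ic[a], a))
    return best, ic.ic[best]


def disjunctive_ancestor_pairs(dag: OntologyDAG, t: str) -> set[frozenset[str]]:
    """Unordered ancestor pairs (a1, a2) that are disjunctive for ``t``.

    a1 and a2 are disjunctive when a directed path a1 ~> t avoids a2 AND a
    directed path a2 ~> t avoids a1 — i.e. each captures an independent
    interpretation of the term.  Endpoints count as "passed through", so no
    pair involving t itself ever qualifies.
    """
    t = dag._check(t)
    anc = sorted(dag.ancestors(t, include_self=True))
    down = dag.graph.reverse(copy=False)  # parent -> child direction

    def reaches_avoiding(a: str, avoid: str) -> bool:
        if a == avoid or t == avoid:
            return False
        seen = {a}
        stack = [a]
        while stack:
            node = stack.pop()
            if node == t:
                return True
            for child in down.successors(node):
                if child != avoid and child not in seen:
                    seen.add(child)
                    stack.append(child)
        return False

    out: set[frozenset[str]] = set()
    for a1, a2 in itertools.combinations(anc, 2):
        if reaches_avoiding(a1, a2) and reaches_avoiding(a2, a1):
            out.add(frozenset((a1, a2)))
    return out


def dca(dag: OntologyDAG, ic: ICTable, t1: str, t2: str) -> TermPairShared:
    """Disjunctive common ancestors (GraSM) and the shared information.

    A common ancestor a belongs to the DCA set iff, for every common
    ancestor a' of strictly greater IC, the pair (a, a') is disjunctive for
    t1 or for t2.  The MICA qualifies vacuously.  Share is the arithmetic
    mean of the IC over the DCA set.
    """
    t1, t2 = dag._check(t1), dag._check(t2)
    _ic_check(ic, t1, t2)
    common = sorted(dag.ancestors(t1) & dag.ancestors(t2) & ic.domain(),
                    key=lambda a: (-ic.ic[a], a))
    pairs = disjunctive_ancestor_pairs(dag, t1) | disjunctive_ancestor_pairs(dag, t2)
    chosen: list[str] = []
    for a in common:
        higher = [b for b in common if ic.ic[b] > ic.ic[a]]
        if all(frozenset((a, b)) in pairs for b in higher):
            chosen.append(a)
    m, m_ic = mica(dag, ic, t1, t2)
    share = float(np.mean([ic.ic[a] for a in chosen]))
    return TermPairShared(mica=m, mica_ic=m_ic, dca=frozenset(chosen), share=share)


def wang_contributions(dag: OntologyDAG, t: str, w_e: float = DEFAULT_WE) -> SemanticContributionMap:
    """Per-ancestor semantic contributions D_t(a) and their sum SV(t).

    D_t(t) = 1; for an ancestor a, D_t(a) = w_e * max over children c of a
    inside the ancestor sub-DAG of D_t(c) — the best-path edge-weight
    product, computed by dynamic programming over a topological order.
    """
    if not 0 < w_e < 1:
        raise ValueError(f"w_e must lie in (0, 1), got {w_e}")
    t = dag._check(t)
    anc = dag.ancestors(t, include_self=True)
    sub = dag.graph.subgraph(anc)  # edges child -> parent
    contrib: dict[str, float] = {}
    for node in nx.topological_sort(sub):  # children before parents
        if node == t:
            contrib[node] = 1.0
        else:
            contrib[node] = w_e * max(contrib[c] for c in sub.predecessors(node))
    return SemanticContributionMap(target=t, contributions=contrib, w_e=w_e)


def _ratio(num: float, den: float) -> float:
    """num/den with the 0/0 (root vs root) convention resolving to 1."""
    if den == 0:
        return 1.0
    return num / den


def term_similarity(dag: OntologyDAG, ic: ICTable | None, t1: str, t2: str,
                    measure: str = "lin", w_e: float = DEFAULT_WE) -> float:
    """Similarity of two terms under one of the ten measures.

    ``ic`` may be None for the structure-only Wang measure.
    """
    measure = measure.lower()
    if measure not in MEASURES:
        raise ValueError(f"unknown measure {measure!r}; choose from {MEASURES}")
    t1, t2 = dag._check(t1), dag._check(t2)

    if measure == "wang":
        c1 = wang_contributions(dag, t1, w_e)
        c2 = wang_contributions(dag, t2, w_e)
        shared = set(c1.contributions) & set(c2.contributions)
        num = sum(c1.contributions[a] + c2.contributions[a] for a in shared)
        return num / (c1.sv + c2.sv)

    if ic is None:
        raise MeasureDomainError(f"measure {measure!r} needs an ICTable")
    _ic_check(ic, t1, t2)
    i1, i2 = ic.ic[t1], ic.ic[t2]

    if measure == "gic":
        a1 = dag.ancestors(t1) & ic.domain()
        a2 = dag.ancestors(t2) & ic.domain()
        num = sum(ic.ic[a] for a in a1 & a2)
        den = sum(ic.ic[a] for a in a1 | a2)
        return _ratio(num, den)

    m, im = mica(dag, ic, t1, t2)
    if measure == "resnik":
        return im
    if measure == "lin":
        return _ratio(2 * im, i1 + i2)
    if measure == "jc":
        return 1.0 - min(1.0, i1 + i2 - 2 * im)
    if measure == "rel":
        return _ratio(2 * im, i1 + i2) * (1.0 - ic.p[m])
    if measure == "simic":
        return _ratio(2 * im, i1 + i2) * (1.0 - 1.0 / (1.0 + im))

    shared = dca(dag, ic, t1, t2)
    if measure == "coutoresnik":
        return shared.share
    if measure == "coutolin":
        return _ratio(2 * shared.share, i1 + i2)
    return 1.0 - min(1.0, i1 + i2 - 2 * shared.share)  # coutojc


def term_similarity_matrix(dag: OntologyDAG, ic: ICTable | None, terms: list[str],
                           measure: str = "lin", w_e: float = DEFAULT_WE) -> pd.DataFrame:
    """Symmetric labelled similarity matrix over a term list.

    Each unordered pair is computed once; the diagonal holds the measure's
    self-similarity (1 for normalized measures, IC(t) for Resnik, ...).
    """
    terms = [dag._check(t) for t in terms]
    if len(terms) < 2:
        raise ValueError("need at least two terms")
    if len(set(terms)) != len(terms):
        raise ValueError("duplicate terms in list")
    n = len(terms)
    vals = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            s = term_similarity(dag, ic, terms[i], terms[j], measure, w_e)
            vals[i, j] = vals[j, i] = s
    return pd.DataFrame(vals, index=terms, columns=terms)


def write_matrix(df: pd.DataFrame, path: str, **metadata) -> None:
    """Write a labelled similarity matrix as TSV with #key=value metadata."""
    with open(path, "w") as fh:
        for k, v in metadata.items():
            fh.write(f"#{k}={v}\n")
        df.to_csv(fh, sep="\t")


def read_matrix(path: str) -> tuple[pd.DataFrame, dict[str, str]]:
    """Read a matrix written by :func:`write_matrix`."""
    meta: dict[str, str] = {}
    with open(path) as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            if line.startswith("#"):
                k, _, v = line[1:].rstrip("\n").partition("=")
                meta[k] = v
                pos = fh.tell()
            else:
                fh.seek(pos)
                break
        df = pd.read_csv(fh, sep="\t", index_col=0)
    return df, meta
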