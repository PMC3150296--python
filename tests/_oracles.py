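"""Independent brute-force oracles used to pin expected values.

Everything here is deliberately naive — exhaustive path enumeration,
exhaustive subset enumeration, direct formula evaluation — and shares no
code path with the package implementations it checks.
"""

from __future__ import annotations

import itertools
import math
from math import comb

import networkx as nx
import numpy as np


def all_down_paths(dag, a: str, t: str) -> list[list[str]]:
    """Every directed path a -> t following parent-to-child edges."""
    if a == t:
        return [[t]]
    down = dag.graph.reverse(copy=False)
    return [list(p) for p in nx.all_simple_paths(down, a, t)]


def oracle_disjunctive_pairs(dag, t: str) -> set[frozenset]:
    """Disjunctive ancestor pairs of t by exhaustive path enumeration."""
    anc = sorted(dag.ancestors(t, include_self=True))
    out = set()
    for a1, a2 in itertools.combinations(anc, 2):
        p1 = any(a2 not in path for path in all_down_paths(dag, a1, t))
        p2 = any(a1 not in path for path in all_down_paths(dag, a2, t))
        if p1 and p2:
            out.add(frozenset((a1, a2)))
    return out


def oracle_dca(dag, ic, t1: str, t2: str) -> tuple[set, float]:
    """GraSM DCA set and Share by direct application of the rule."""
    common = dag.ancestors(t1) & dag.ancestors(t2) & set(ic.ic)
    pairs = oracle_disjunctive_pairs(dag, t1) | oracle_disjunctive_pairs(dag, t2)
    dca = set()
    for a in common:
        if all(frozenset((a, b)) in pairs
               for b in common if ic.ic[b] > ic.ic[a]):
            dca.add(a)
    share = sum(ic.ic[a] for a in dca) / len(dca)
    return dca, share


def oracle_wang_contribution(dag, a: str, t: str, w_e: float) -> float:
    """Best-path edge-weight product by enumerating every path a -> t."""
    paths = all_down_paths(dag, a, t)
    return max(w_e ** (len(p) - 1) for p in paths)


def oracle_wang_similarity(dag, t1: str, t2: str, w_e: float = 0.7) -> float:
    anc1 = dag.ancestors(t1, include_self=True)
    anc2 = dag.ancestors(t2, include_self=True)
    c1 = {a: oracle_wang_contribution(dag, a, t1, w_e) for a in anc1}
    c2 = {a: oracle_wang_contribution(dag, a, t2, w_e) for a in anc2}
    shared = anc1 & anc2
    return sum(c1[a] + c2[a] for a in shared) / (sum(c1.values()) + sum(c2.values()))


def oracle_ic_similarity(dag, ic, t1: str, t2: str, measure: str) -> float:
    """IC-based measures by direct formula evaluation."""
    common = dag.ancestors(t1) & dag.ancestors(t2) & set(ic.ic)
    im = max(ic.ic[a] for a in common)
    p_mica = min(ic.p[a] for a in common if ic.ic[a] == im)
    i1, i2 = ic.ic[t1], ic.ic[t2]
    ratio = 1.0 if i1 + i2 == 0 else 2 * im / (i1 + i2)
    if measure == "resnik":
        return im
    if measure == "lin":
        return ratio
    if measure == "jc":
        return 1 - min(1.0, i1 + i2 - 2 * im)
    if measure == "rel":
        return ratio * (1 - p_mica)
    if measure == "simic":
        return ratio * (1 - 1 / (1 + im))
    if measure == "gic":
        a1 = dag.ancestors(t1) & set(ic.ic)
        a2 = dag.ancestors(t2) & set(ic.ic)
        den = sum(ic.ic[a] for a in a1 | a2)
        return 1.0 if den == 0 else sum(ic.ic[a] for a in a1 & a2) / den
    sh = oracle_dca(dag, ic, t1, t2)[1]
    if measure == "coutoresnik":
        return sh
    if measure == "coutolin":
        return 1.0 if i1 + i2 == 0 else 2 * sh / (i1 + i2)
    if measure == "coutojc":
        return 1 - min(1.0, i1 + i2 - 2 * sh)
    raise ValueError(measure)


def oracle_hypergeom_upper(N: int, M: int, k: int, x: int) -> float:
    """Upper-tail mass by summing the exact pmf with integer binomials."""
    total = comb(N, k)
    return sum(comb(M, i) * comb(N - M, k - i)
               for i in range(x, min(M, k) + 1)) / total


def oracle_hypergeom_enumeration(N: int, M: int, k: int, x: int) -> float:
    """P(X >= x) by enumerating every k-subset of an N-element universe."""
    genes = range(N)
    annotated = set(range(M))
    hits = sum(1 for s in itertools.combinations(genes, k)
               if len(annotated & set(s)) >= x)
    return hits / comb(N, k)


def oracle_bh(p: list[float]) -> list[float]:
    """Benjamini–Hochberg step-up by the textbook recurrence."""
    n = len(p)
    order = sorted(range(n), key=lambda i: p[i])
    q = [0.0] * n
    prev = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        prev = min(prev, p[i] * n / rank)
        q[i] = min(prev, 1.0)
    return q


def oracle_aggregation(s: np.ndarray, method: str) -> float:
    """Term-set aggregation by literal formula evaluation."""
    row_max = [max(row) for row in s]
    col_max = [max(col) for col in s.T]
    m, n = s.shape
    if method == "max":
        return max(map(max, s))
    if method == "mean":
        return sum(map(sum, s)) / (m * n)
    row_score = sum(row_max) / m
    col_score = sum(col_max) / n
    if method == "funsimmax":
        return max(row_score, col_score)
    if method == "funsimavg":
        return (row_score + col_score) / 2
    return (sum(row_max) + sum(col_max)) / (m + n)  # bma


def oracle_module_fraction(sim: np.ndarray, member_idx: list[int]) -> float:
    """Exact fraction of same-size index subsets with mean >= observed."""
    def mean_off(idx):
        pairs = list(itertools.combinations(idx, 2))
        return sum(sim[i, j] for i, j in pairs) / len(pairs)

    obs = mean_off(member_idx)
    subsets = list(itertools.combinations(range(sim.shape[0]), len(member_idx)))
    return sum(1 for s in subsets if mean_off(s) >= obs) / len(subsets)
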