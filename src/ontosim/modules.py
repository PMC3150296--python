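"""Similarity-driven module detection and permutation significance.

A labelled similarity matrix is converted to a distance matrix (d = 1 - s,
after max-rescaling when the measure is unnormalized), clustered by
average-linkage (UPGMA) hierarchical clustering, and cut either at a constant
height or by an adaptive "tree" branch-cutting that recursively splits the
dendrogram at its largest merge-height gaps.  Module significance is assessed
by permutation: the observed within-module mean similarity is compared with
the means of random same-size label subsets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import squareform

from .enrichment import bh_fdr


@dataclass
class ModuleAssignment:
    """Label → module number; 0 marks unassigned ("grey") items.

    Module numbers are 1..K, contiguous, ordered by decreasing size.
    """

    labels: dict[str, int]
    min_size: int

    def members(self, module: int) -> list[str]:
        return [l for l, m in self.labels.items() if m == module]

    @property
    def n_modules(self) -> int:
        return max(self.labels.values(), default=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(sorted(self.labels.items()), columns=["id", "module"])


@dataclass
class ModuleStats:
    module: int
    size: int
    mean_similarity: float
    p_value: float = float("nan")
    fdr: float = float("nan")


def similarity_to_distance(sim: pd.DataFrame) -> pd.DataFrame:
    """d = 1 - s with zero diagonal; unnormalized matrices are max-rescaled."""
    vals = sim.to_numpy(dtype=float)
    if vals.shape[0] != vals.shape[1] or not np.allclose(vals, vals.T, atol=1e-10):
        raise ValueError("similarity matrix must be square and symmetric")
    top = vals.max()
    if top > 1.0:
        vals = vals / top
    d = 1.0 - vals
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2  # restore exact symmetry after float ops
    return pd.DataFrame(d, index=sim.index, columns=sim.columns)


def average_linkage(dist: pd.DataFrame) -> np.ndarray:
    """UPGMA merge history (scipy linkage matrix) of a distance matrix."""
    if len(dist) < 2:
        raise ValueError("need at least two items to cluster")
    condensed = squareform(dist.to_numpy(dtype=float), checks=True)
    return linkage(condensed, method="average")


def _components_below(Z: np.ndarray, height: float) -> list[list[int]]:
    """Connected components of merges strictly below ``height`` (leaf indices)."""
    n = Z.shape[0] + 1
    comp: dict[int, list[int]] = {i: [i] for i in range(n)}
    for i, (a, b, h, _) in enumerate(Z):
        if h < height:
            merged = comp.pop(int(a)) + comp.pop(int(b))
            comp[n + i] = merged
    return list(comp.values())


def _number_modules(groups: list[list[str]], all_labels, min_size: int) -> ModuleAssignment:
    keep = [g for g in groups if len(g) >= min_size]
    keep.sort(key=lambda g: (-len(g), sorted(g)[0]))
    labels = {l: 0 for l in all_labels}
    for num, g in enumerate(keep, start=1):
        for l in g:
            labels[l] = num
    return ModuleAssignment(labels=labels, min_size=min_size)


def cut_static(Z: np.ndarray, labels, height: float, min_size: int = 1) -> ModuleAssignment:
    """Constant-height cut: clusters merged strictly below ``height``.

    Components smaller than ``min_size`` stay unassigned (module 0).
    """
    if height < 0:
        raise ValueError("height must be >= 0")
    labels = list(labels)
    groups = [[labels[i] for i in comp] for comp in _components_below(Z, height)]
    return _number_modules(groups, labels, min_size)


def cut_dynamic(Z: np.ndarray, labels, min_size: int = 2,
                gap_frac: float = 0.3) -> ModuleAssignment:
    """Adaptive top-down ("tree") branch cutting.

    Recursively: within a branch, locate the largest gap between consecutive
    sorted merge heights; if that gap exceeds ``gap_frac`` times the full
    dendrogram height, cut in the middle of the gap and recurse into the
    resulting sub-branches; otherwise accept the branch as one module when
    it has at least ``min_size`` leaves.  Every returned module is therefore
    a contiguous dendrogram branch with >= min_size leaves; leaves of
    rejected branches stay unassigned.
    """
    if min_size < 2:
        raise ValueError("min_size must be >= 2")
    labels = list(labels)
    root = to_tree(Z)
    scale = root.dist
    groups: list[list[str]] = []

    def heights(node) -> list[float]:
        out = []
        stack = [node]
        while stack:
            nd = stack.pop()
            if not nd.is_leaf():
                out.append(nd.dist)
                stack.extend([nd.left, nd.right])
        return sorted(out)

    def leaf_labels(node) -> list[str]:
        return [labels[i] for i in node.pre_order(lambda x: x.id)]

    def component_roots(node, cut: float):
        if node.is_leaf() or node.dist < cut:
            return [node]
        return component_roots(node.left, cut) + component_roots(node.right, cut)

    def walk(node):
        if node.get_count() < min_size:
            return
        hs = heights(node)
        if len(hs) >= 2:
            gaps = np.diff(hs)
            i = int(np.argmax(gaps))
            if scale > 0 and gaps[i] >= gap_frac * scale:
                cut = (hs[i] + hs[i + 1]) / 2
                for sub in component_roots(node, cut):
                    walk(sub)
                return
        groups.append(leaf_labels(node))

    walk(root)
    return _number_modules(groups, labels, min_size)


def to_newick(Z: np.ndarray, labels) -> str:
    """Dendrogram as a Newick string with heights encoded as branch lengths."""
    labels = list(labels)
    root = to_tree(Z)

    def fmt(node, parent_dist: float) -> str:
        length = max(parent_dist - node.dist, 0.0)
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        return (f"({fmt(node.left, node.dist)},{fmt(node.right, node.dist)})"
                f":{length:.6g}")

    return fmt(root, root.dist) + ";"


def permutation_threshold(sim_fn, pool, sample_size: int, reps: int = 100,
                          percentile: float = 99.0, seed: int = 0) -> float:
    """Percentile of a permutation background of pairwise similarities.

    ``sim_fn`` maps a list of IDs to a labelled square similarity matrix;
    ``reps`` random subsets of ``sample_size`` IDs are drawn without
    replacement from ``pool`` and all their off-diagonal similarities pooled.
    """
    if not 0 < percentile < 100:
        raise ValueError("percentile must lie strictly between 0 and 100")
    pool = list(pool)
    if sample_size > len(pool):
        raise ValueError("sample_size exceeds pool size")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    values = []
    for _ in range(reps):
        subset = list(rng.choice(pool, size=sample_size, replace=False))
        m = np.asarray(sim_fn(subset), dtype=float)
        iu = np.triu_indices(m.shape[0], k=1)
        values.append(m[iu])
    return float(np.percentile(np.concatenate(values), percentile))


def _mean_offdiag(vals: np.ndarray, idx: np.ndarray) -> float:
    sub = vals[np.ix_(idx, idx)]
    iu = np.triu_indices(len(idx), k=1)
    return float(sub[iu].mean())


def module_significance(sim: pd.DataFrame, assignment: ModuleAssignment,
                        reps: int = 1000, seed: int = 0) -> list[ModuleStats]:
    """Permutation p-value of each module's mean within-module similarity.

    p = (b + 1) / (reps + 1) where b counts random same-size subsets of the
    matrix labels whose mean pairwise similarity is >= the observed one
    (add-one smoothing keeps p >= 1/(reps+1)).  FDR across modules by BH.
    """
    label_pos = {l: i for i, l in enumerate(sim.index)}
    vals = sim.to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    stats: list[ModuleStats] = []
    n = len(sim)
    for module in range(1, assignment.n_modules + 1):
        members = assignment.members(module)
        missing = [m for m in members if m not in label_pos]
        if missing:
            raise ValueError(f"module {module} members absent from matrix: {missing}")
        idx = np.array([label_pos[m] for m in members])
        obs = _mean_offdiag(vals, idx)
        b = 0
        for _ in range(reps):
            rand = rng.choice(n, size=len(idx), replace=False)
            if _mean_offdiag(vals, rand) >= obs:
                b += 1
        stats.append(ModuleStats(module=module, size=len(idx), mean_similarity=obs,
                                 p_value=(b + 1) / (reps + 1)))
    for st, q in zip(stats, bh_fdr([s.p_value for s in stats])):
        st.fdr = q
    return stats


def significant_pairs(sim: pd.DataFrame, threshold: float) -> pd.DataFrame:
    """Edge list (id1, id2, similarity) of pairs with similarity >= threshold."""
    rows = []
    ids = list(sim.index)
    vals = sim.to_numpy(dtype=float)
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            if vals[i, j] >= threshold:
                rows.append((ids[i], ids[j], vals[i, j]))
    return pd.DataFrame(rows, columns=["id1", "id2", "similarity"])


def stats_to_frame(stats: list[ModuleStats]) -> pd.DataFrame:
    return pd.DataFrame([(s.module, s.size, s.mean_similarity, s.p_value, s.fdr)
                         for s in stats],
                        columns=["module", "size", "mean_similarity", "p_value", "fdr"])
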