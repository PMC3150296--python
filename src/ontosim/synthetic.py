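"""Deterministic fixtures and random generators for ontologies and corpora.

Everything here exists so the similarity, enrichment and module-detection
machinery can be exercised without any external ontology download: a small
hand-analysable nine-term fixture, layered random DAG and corpus generators
(seeded, bit-reproducible), and planted-partition similarity matrices with
known ground-truth modules.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .corpus import AnnotationCorpus, load_annotations
from .ontology import OntologyDAG, parse_obo

TOY9_OBO = """\
format-version: 1.2
ontology: toy9

[Term]
id: TOY:0000000
name: root

[Term]
id: TOY:0000001
name: A
is_a: TOY:0000000 ! root

[Term]
id: TOY:0000002
name: B
is_a: TOY:0000000 ! root

[Term]
id: TOY:0000003
name: C
is_a: TOY:0000001 ! A

[Term]
id: TOY:0000004
name: D
is_a: TOY:0000001 ! A
is_a: TOY:0000002 ! B

[Term]
id: TOY:0000005
name: E
is_a: TOY:0000003 ! C

[Term]
id: TOY:0000006
name: F
is_a: TOY:0000004 ! D

[Term]
id: TOY:0000098
name: obsolete padding one
is_obsolete: true

[Term]
id: TOY:0000099
name: obsolete padding two
is_obsolete: true
"""

#: short aliases used throughout tests and examples
TOY9_ALIASES = {
    "R": "TOY:0000000", "A": "TOY:0000001", "B": "TOY:0000002",
    "C": "TOY:0000003", "D": "TOY:0000004", "E": "TOY:0000005",
    "F": "TOY:0000006",
}

TOY9_ANNOTATIONS = """\
#gene\tterm
g1\tTOY:0000005
g2\tTOY:0000005
g2\tTOY:0000006
g3\tTOY:0000006
g4\tTOY:0000003
g5\tTOY:0000004
g6\tTOY:0000002
g7\tTOY:0000001
g8\tTOY:0000000
"""


@dataclass
class FixtureBundle:
    """A DAG, a matching corpus and a table of hand-derived expectations."""

    dag: OntologyDAG
    corpus: AnnotationCorpus
    expected: dict[str, float] = field(default_factory=dict)
    aliases: dict[str, str] = field(default_factory=dict)

    def acc(self, alias: str) -> str:
        return self.aliases.get(alias, alias)


def fixture_toy9() -> FixtureBundle:
    """The canonical nine-term fixture.

    Structure (child is-a parent): A,B -> R; C -> A; D -> A,B; E -> C;
    F -> D; plus two obsolete padding terms.  Eight genes g1..g8 annotate
    E, {E,F}, F, C, D, B, A, R respectively.  The ``expected`` table holds
    quantities small enough to derive by hand (natural-log IC):

    counts E,F = 2; C,D = 3; A = 6; B = 4; R = 8, hence p(A) = 0.75,
    IC(E) = -ln(1/4), the MICA of (E, F) is A, and the tabulated
    similarities follow by direct evaluation of the measure formulas.
    """
    dag = parse_obo(TOY9_OBO)
    corpus = load_annotations(TOY9_ANNOTATIONS, dag)
    ln = np.log
    ic_A = float(-ln(6 / 8))
    ic_E = float(-ln(2 / 8))
    ic_C = float(-ln(3 / 8))
    lin_EC = 2 * ic_C / (ic_E + ic_C)
    lin_FC = 2 * ic_A / (ic_E + ic_C)
    expected = {
        "p_A": 6 / 8,
        "ic_A": ic_A,                      # 0.2877
        "ic_E": ic_E,                      # 1.3863
        "count_A": 6,
        "count_E": 2,
        "mica_EF_ic": ic_A,
        "share_EF": ic_A / 2,              # DCA {A, R} -> 0.1438
        "resnik_EF": ic_A,
        "lin_EF": 2 * ic_A / (2 * ic_E),   # 0.2075
        "rel_EF": 2 * ic_A / (2 * ic_E) * (1 - 6 / 8),
        "gic_EF": ic_A / (2 * ic_E + 2 * ic_C + ic_A + float(-ln(4 / 8))),
        "wang_EF": (2 * 0.49 + 2 * 0.343) / (2.533 + 3.023),
        "coutolin_EF": ic_A / (2 * ic_E),
        "bma_lin_g2_g4": (lin_EC + lin_FC + lin_EC) / 3,  # 0.6335
        "enrich_E_p": 6 / 56,              # gene set {g1,g2,g3}, N=8 M=2 k=3 x=2
    }
    return FixtureBundle(dag=dag, corpus=corpus, expected=expected,
                         aliases=dict(TOY9_ALIASES))


@dataclass(frozen=True)
class GeneratorParams:
    """Knobs of the random ontology/corpus generators."""

    n_terms: int = 30
    n_genes: int = 40
    max_parents: int = 2
    depth_target: int = 4
    annotations_min: int = 1
    annotations_max: int = 4
    seed: int = 0

    def __post_init__(self):
        if min(self.n_terms, self.n_genes + 1, self.max_parents,
               self.depth_target, self.annotations_min) < 1:
            raise ValueError("all generator counts must be positive")
        if self.annotations_max < self.annotations_min:
            raise ValueError("annotations_max < annotations_min")


def random_ontology(params: GeneratorParams) -> OntologyDAG:
    """Layered random DAG: acyclic by construction, reproducible by seed.

    Terms are spread over depths 1..depth_target below a single root; every
    non-root term draws 1..max_parents parents from strictly shallower
    layers, so multi-parent rate rises with ``max_parents``.
    """
    rng = np.random.default_rng(params.seed)
    accs = [f"RND:{i:07d}" for i in range(params.n_terms)]
    root = accs[0]
    layers: list[list[str]] = [[root]]
    rest = accs[1:]
    depth = min(params.depth_target, max(1, len(rest)))
    splits = np.array_split(np.array(rest), depth)
    layers += [list(s) for s in splits if len(s)]
    from .ontology import OntologyTerm
    terms = [OntologyTerm(root, "root")]
    for li in range(1, len(layers)):
        shallower = [t for lay in layers[:li] for t in lay]
        for acc in layers[li]:
            k = int(rng.integers(1, params.max_parents + 1))
            k = min(k, len(shallower))
            parents = rng.choice(shallower, size=k, replace=False)
            terms.append(OntologyTerm(acc, f"term {acc}", frozenset(parents.tolist())))
    return OntologyDAG(terms)


def random_corpus(dag: OntologyDAG, params: GeneratorParams,
                  leaf_coverage: bool = False) -> AnnotationCorpus:
    """Random gene → term annotations (root excluded from the draw).

    With ``leaf_coverage`` a sentinel gene is added per leaf so every term
    ends up with a positive propagated count (p(t) > 0 everywhere).
    """
    rng = np.random.default_rng(params.seed + 1)
    pool = sorted(t for t in dag.live_terms() if t != dag.root)
    direct: dict[str, set[str]] = {}
    for i in range(params.n_genes):
        k = int(rng.integers(params.annotations_min, params.annotations_max + 1))
        k = min(k, len(pool))
        direct[f"gene{i:04d}"] = set(rng.choice(pool, size=k, replace=False).tolist())
    if leaf_coverage:
        for j, leaf in enumerate(sorted(dag.leaves())):
            direct[f"sentinel{j:04d}"] = {leaf}
    return AnnotationCorpus(direct)


def planted_similarity(blocks: list[int], within: float = 0.9, between: float = 0.1,
                       noise_sd: float = 0.02, seed: int = 0) -> pd.DataFrame:
    """Block-structured similarity matrix with known ground-truth modules.

    Off-diagonal entries are ``within`` inside a block and ``between``
    across blocks, plus Gaussian noise, symmetrized and clipped to [0, 1];
    the diagonal is 1.  Ground-truth labels are recoverable from the index:
    items are named ``b<block>_<i>``.
    """
    if not 0 <= between < within <= 1:
        raise ValueError("need 0 <= between < within <= 1")
    rng = np.random.default_rng(seed)
    n = sum(blocks)
    ids, truth = [], []
    for b, size in enumerate(blocks, start=1):
        ids += [f"b{b}_{i}" for i in range(size)]
        truth += [b] * size
    truth_arr = np.array(truth)
    base = np.where(truth_arr[:, None] == truth_arr[None, :], within, between)
    noise = rng.normal(0.0, noise_sd, size=(n, n))
    vals = base + (noise + noise.T) / 2
    vals = np.clip(vals, 0.0, 1.0)
    np.fill_diagonal(vals, 1.0)
    df = pd.DataFrame(vals, index=ids, columns=ids)
    df.attrs["truth"] = dict(zip(ids, truth))
    return df
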