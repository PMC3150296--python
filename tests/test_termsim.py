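import itertools
import math

import numpy as np
import pytest

from ontosim import (GeneratorParams, MEASURES, NORMALIZED_MEASURES, dca,
                     disjunctive_ancestor_pairs, information_content,
                     load_annotations, mica, random_corpus, random_ontology,
                     term_similarity, term_similarity_matrix, wang_contributions)
from ontosim.termsim import MeasureDomainError, read_matrix, write_matrix

from _oracles import (oracle_dca, oracle_disjunctive_pairs, oracle_ic_similarity,
                      oracle_wang_similarity)


def test_mica_fixture(toy9, toy9_ic):
    E, F, C = toy9.acc("E"), toy9.acc("F"), toy9.acc("C")
    acc, ic_val = mica(toy9.dag, toy9_ic, E, F)
    assert acc == toy9.acc("A")
    assert ic_val == pytest.approx(0.2877, abs=1e-4)
    assert mica(toy9.dag, toy9_ic, E, E)[0] == E
    assert mica(toy9.dag, toy9_ic, E, C)[0] == C  # containment case


def test_disjunctive_pairs_fixture(toy9):
    F = toy9.acc("F")
    pairs = disjunctive_ancestor_pairs(toy9.dag, F)
    assert frozenset((toy9.acc("A"), toy9.acc("B"))) in pairs
    assert pairs == oracle_disjunctive_pairs(toy9.dag, F)
    # single-path chain: no pair is disjunctive
    assert disjunctive_ancestor_pairs(toy9.dag, toy9.acc("E")) == set()


def test_dca_fixture(toy9, toy9_ic):
    E, F = toy9.acc("E"), toy9.acc("F")
    shared = dca(toy9.dag, toy9_ic, E, F)
    assert shared.dca == frozenset({toy9.acc("A"), toy9.acc("R")})
    assert shared.share == pytest.approx(0.1438, abs=1e-4)
    assert shared.mica in shared.dca
    assert shared.share <= shared.mica_ic
    self_shared = dca(toy9.dag, toy9_ic, E, E)
    assert self_shared.dca == frozenset({E})
    assert self_shared.share == pytest.approx(toy9_ic.ic[E])


def test_wang_contributions_fixture(toy9):
    E, F = toy9.acc("E"), toy9.acc("F")
    ce = wang_contributions(toy9.dag, E)
    assert ce.contributions[E] == 1.0
    assert sorted(ce.contributions.values()) == pytest.approx([0.343, 0.49, 0.7, 1.0])
    assert ce.sv == pytest.approx(2.533)
    cf = wang_contributions(toy9.dag, F)
    assert cf.contributions[toy9.acc("R")] == pytest.approx(0.343)
    assert cf.sv == pytest.approx(3.023)
    assert wang_contributions(toy9.dag, toy9.acc("R")).sv == 1.0
    with pytest.raises(ValueError):
        wang_contributions(toy9.dag, E, w_e=1.5)


@pytest.mark.parametrize("measure,key", [
    ("resnik", "resnik_EF"), ("lin", "lin_EF"), ("rel", "rel_EF"),
    ("gic", "gic_EF"), ("wang", "wang_EF"), ("coutoresnik", "share_EF"),
    ("coutolin", "coutolin_EF"),
])
def test_similarity_fixture_values(toy9, toy9_ic, measure, key):
    got = term_similarity(toy9.dag, toy9_ic, toy9.acc("E"), toy9.acc("F"), measure)
    assert got == pytest.approx(toy9.expected[key], abs=1e-4)


def test_self_similarity(toy9, toy9_ic):
    E = toy9.acc("E")
    for m in ("lin", "wang", "jc", "gic", "coutolin", "coutojc", "rel"):
        if m == "rel":
            continue  # rel(t,t) = 1 - p(mica), not 1
        assert term_similarity(toy9.dag, toy9_ic, E, E, m) == pytest.approx(1.0)
    assert term_similarity(toy9.dag, toy9_ic, E, E, "resnik") == toy9_ic.ic[E]


def test_unknown_measure_and_domain_errors(toy9, toy9_ic):
    E = toy9.acc("E")
    with pytest.raises(ValueError, match="unknown measure"):
        term_similarity(toy9.dag, toy9_ic, E, E, "cosine")
    sparse = information_content(toy9.dag, load_annotations(f"g1\t{E}\n", toy9.dag))
    with pytest.raises(MeasureDomainError, match="TOY:0000006"):
        term_similarity(toy9.dag, sparse, E, toy9.acc("F"), "lin")
    # wang needs no IC at all
    assert term_similarity(toy9.dag, None, E, toy9.acc("F"), "wang") > 0


def test_matrix_fixture(toy9, toy9_ic):
    E, F, C = toy9.acc("E"), toy9.acc("F"), toy9.acc("C")
    df = term_similarity_matrix(toy9.dag, toy9_ic, [E, F, C], "lin")
    assert np.allclose(df.values, df.values.T)
    assert np.allclose(np.diag(df.values), 1.0)
    assert df.loc[E, F] == pytest.approx(0.2075, abs=1e-4)
    pair = term_similarity_matrix(toy9.dag, toy9_ic, [E, F], "lin")
    assert pair.loc[E, F] == pytest.approx(0.2075, abs=1e-4)
    again = term_similarity_matrix(toy9.dag, toy9_ic, [E, F, C], "lin")
    assert df.equals(again)


def test_matrix_tsv_roundtrip(toy9, toy9_ic, tmp_path):
    E, F = toy9.acc("E"), toy9.acc("F")
    df = term_similarity_matrix(toy9.dag, toy9_ic, [E, F], "wang")
    path = tmp_path / "m.tsv"
    write_matrix(df, str(path), measure="wang", w_e=0.7)
    back, meta = read_matrix(str(path))
    assert meta["measure"] == "wang" and float(meta["w_e"]) == 0.7
    assert np.allclose(back.values, df.values)
    assert list(back.index) == [E, F]


def _random_fixture(seed, n_terms=14, max_parents=3):
    dag = random_ontology(GeneratorParams(n_terms=n_terms, max_parents=max_parents, seed=seed))
    corpus = random_corpus(dag, GeneratorParams(n_genes=20, seed=seed), leaf_coverage=True)
    return dag, corpus, information_content(dag, corpus)


@pytest.mark.parametrize("seed", range(5))
def test_measure_invariants_random(seed):
    """Symmetry, ranges, simIC <= Lin, Rel <= Lin on random DAGs."""
    dag, corpus, ic = _random_fixture(seed)
    rng = np.random.default_rng(seed)
    terms = list(rng.choice(sorted(ic.domain()), size=6, replace=False))
    max_ic = max(ic.ic.values())
    for t1, t2 in itertools.combinations(terms, 2):
        vals = {m: term_similarity(dag, ic, t1, t2, m) for m in MEASURES}
        for m, v in vals.items():
            assert term_similarity(dag, ic, t2, t1, m) == pytest.approx(v), m
            if m in NORMALIZED_MEASURES:
                assert -1e-12 <= v <= 1 + 1e-12, m
            else:
                assert -1e-12 <= v <= max_ic + 1e-12, m
        assert vals["simic"] <= vals["lin"] + 1e-12
        assert vals["rel"] <= vals["lin"] + 1e-12


@pytest.mark.parametrize("seed", range(3))
def test_log_base_invariance_of_ratio_measures(seed):
    dag, corpus, _ = _random_fixture(seed)
    ic_e = information_content(dag, corpus, math.e)
    ic_2 = information_content(dag, corpus, 2.0)
    rng = np.random.default_rng(seed)
    terms = list(rng.choice(sorted(ic_e.domain()), size=5, replace=False))
    for t1, t2 in itertools.combinations(terms, 2):
        for m in ("lin", "rel", "gic", "coutolin"):
            assert term_similarity(dag, ic_e, t1, t2, m) == \
                pytest.approx(term_similarity(dag, ic_2, t1, t2, m)), m
        assert term_similarity(dag, None, t1, t2, "wang") == \
            term_similarity(dag, None, t2, t1, "wang")


def test_wang_ignores_corpus(toy9):
    """Wang is structure-only: it never touches the annotation corpus."""
    E, F = toy9.acc("E"), toy9.acc("F")
    assert term_similarity(toy9.dag, None, E, F, "wang") == \
        pytest.approx(toy9.expected["wang_EF"], abs=1e-4)


@pytest.mark.parametrize("seed", range(10))
def test_dca_matches_path_enumeration_oracle(seed):
    dag, corpus, ic = _random_fixture(seed, n_terms=12)
    for t in dag.live_terms():
        assert disjunctive_ancestor_pairs(dag, t) == oracle_disjunctive_pairs(dag, t)
    rng = np.random.default_rng(seed)
    terms = sorted(ic.domain())
    for t1, t2 in [rng.choice(terms, 2) for _ in range(5)]:
        got = dca(dag, ic, t1, t2)
        exp_set, exp_share = oracle_dca(dag, ic, t1, t2)
        assert set(got.dca) == exp_set
        assert got.share == pytest.approx(exp_share)


@pytest.mark.parametrize("seed", range(5))
def test_tree_reduction(seed):
    """On trees the Couto variants coincide exactly with their originals."""
    dag = random_ontology(GeneratorParams(n_terms=14, max_parents=1, seed=seed))
    corpus = random_corpus(dag, GeneratorParams(n_genes=20, seed=seed), leaf_coverage=True)
    ic = information_content(dag, corpus)
    terms = sorted(ic.domain())
    rng = np.random.default_rng(seed)
    for t1, t2 in [rng.choice(terms, 2) for _ in range(8)]:
        for base, couto in (("resnik", "coutoresnik"), ("lin", "coutolin"), ("jc", "coutojc")):
            assert term_similarity(dag, ic, t1, t2, base) == \
                pytest.approx(term_similarity(dag, ic, t1, t2, couto), abs=1e-12)


@pytest.mark.parametrize("seed", range(4))
def test_similarity_matches_formula_oracle(seed):
    dag, corpus, ic = _random_fixture(seed, n_terms=12)
    rng = np.random.default_rng(seed + 100)
    terms = sorted(ic.domain())
    for t1, t2 in [rng.choice(terms, 2) for _ in range(4)]:
        for m in MEASURES:
            if m == "wang":
                exp = oracle_wang_similarity(dag, t1, t2)
            else:
                exp = oracle_ic_similarity(dag, ic, t1, t2, m)
            assert term_similarity(dag, ic, t1, t2, m) == pytest.approx(exp), m
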