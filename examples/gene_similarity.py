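"""Gene-gene similarity from term-set aggregation.

Each gene is its set of direct term annotations; the pairwise term
similarities between two genes' sets are aggregated by the best-match
average (BMA).  Prints the full 8 x 8 matrix for the fixture corpus under
Lin + BMA and the single pair used as the worked example throughout the
test suite.
"""

from ontosim import fixture_toy9, gene_similarity, gene_similarity_matrix, information_content

bundle = fixture_toy9()
ic = information_content(bundle.dag, bundle.corpus)

sim = gene_similarity_matrix(bundle.dag, ic, bundle.corpus,
                             bundle.corpus.genes, measure="lin", method="bma")
print("Lin + BMA gene similarity matrix:")
print(sim.round(3).to_string())

pair = gene_similarity(bundle.dag, ic, bundle.corpus, "g2", "g4", "lin", "bma")
print(f"\nBMA-Lin(g2, g4) = {pair:.4f}")
print("g2 is annotated to {E, F} and g4 to {C}; C is an ancestor of E, so the")
print("best matches are strong in one direction and weak in the other.")
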