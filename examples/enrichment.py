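"""Hypergeometric term enrichment of a small gene set.

Tests which ontology terms are over-represented among {g1, g2, g3} (the
genes annotated to the two deepest leaves) relative to the eight-gene
universe.  The filter (minimum propagated count) and layer (minimum depth)
criteria restrict testing to reasonably specific, reasonably populated
terms; FDR is Benjamini-Hochberg across the candidates.
"""

from ontosim import EnrichmentConfig, enrich, fixture_toy9
from ontosim.enrichment import records_to_frame

bundle = fixture_toy9()
records = enrich(bundle.dag, bundle.corpus, ["g1", "g2", "g3"],
                 EnrichmentConfig(filter=2, layer=1))
print(records_to_frame(records).drop(columns="genes").to_string(index=False))
print("\nThe leaves E and F hold 2 of the 3 query genes against 2 of 8 in the")
print("universe (p = 6/56 = 0.107); nothing clears 0.05 at this tiny scale.")
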