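"""Structural queries and subgraph extraction on an ontology DAG.

Parses OBO text, walks ancestors/descendants/depth, and extracts the
induced sub-DAG that has two chosen terms as its leaves -- the structure a
graph viewer would render.
"""

from ontosim import fixture_toy9

bundle = fixture_toy9()
dag = bundle.dag
E, F, D = bundle.acc("E"), bundle.acc("F"), bundle.acc("D")

print(f"root: {dag.root}; live terms: {len(dag)}")
print(f"ancestors(E)   = {sorted(dag.ancestors(E))}")
print(f"depth(F)       = {dag.depth(F)}")
print(f"parents(D)     = {sorted(dag.related_terms(D, 'parents'))}  (multi-parent term)")

sub = dag.induced_graph([E, F])
print(f"\ninduced graph with leaves {{E, F}}: {len(sub)} terms")
print(sub.to_edge_list())
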