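"""Similarity-driven module detection with permutation significance.

Generates a planted-partition similarity matrix (three blocks of known
membership plus noise), clusters it with average linkage, cuts the
dendrogram with the adaptive "tree" branch cutting, and scores each module
by permutation: p is the add-one-smoothed fraction of random same-size
label subsets whose mean pairwise similarity reaches the observed one.
"""

from ontosim import (average_linkage, cut_dynamic, module_significance,
                     planted_similarity, similarity_to_distance)
from ontosim.modules import stats_to_frame

sim = planted_similarity([12, 15, 10], within=0.9, between=0.1,
                         noise_sd=0.02, seed=7)
Z = average_linkage(similarity_to_distance(sim))
assignment = cut_dynamic(Z, sim.index, min_size=8)
stats = module_significance(sim, assignment, reps=999, seed=7)

print(f"detected modules: {assignment.n_modules} (planted: 3)")
print(stats_to_frame(stats).round(4).to_string(index=False))
print("\nEach detected module matches one planted block; within-module mean")
print("similarity ~0.9 is never reached by random label subsets, so every")
print("p-value sits at the smoothing floor 1/(reps+1) = 0.001.")
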