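"""Enumerate branch modules of one chemical class and summarize them.

Every branch of the class dendrogram with at least `min_size` leaves is a
candidate module; each is summarized by its eigen-metabolite (first
principal component of the members' standardized concentration profiles).
"""

from metchem import (
    all_branches,
    cluster_dendrogram,
    detect_clusters,
    generate_concentrations,
    generate_structural_panel,
    wmcsa_summarize,
)

panel, truth = generate_structural_panel(8, seed=1)
conc = generate_concentrations(panel, truth, seed=1)
assignment = detect_clusters(panel, repeats=10, seed=1)

dendro = cluster_dendrogram(assignment, 1)
print(f"class 1 dendrogram over {dendro.n_leaves} metabolites")
print("newick:", dendro.to_newick()[:70], "...")

modules = all_branches(dendro, min_size=3)
print(f"{len(modules)} candidate modules (branches with >= 3 leaves)")

E = wmcsa_summarize(conc, modules)
for mid in E.module_ids:
    print(f"  module {mid}: {len(modules.modules[mid])} members, "
          f"variance explained {E.variance_explained[mid]:.2f}, "
          f"mean member correlation {E.member_correlations[mid]:.2f}")

# Variance explained near 1 means the module's members move together across
# samples: the eigen-metabolite is then a faithful one-number summary.
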