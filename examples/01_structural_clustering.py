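"""Detect chemical classes in a synthetic metabolite panel.

Builds a panel of three structural families (fatty acids, alpha-amino
acids, purine derivatives), runs the structural chain (fingerprints ->
Tanimoto -> MDS -> accuracy-maximization 2D embedding -> silhouette-selected
hierarchical clustering) and compares the detected classes to the planted
families.
"""

from collections import Counter

from metchem import detect_clusters, generate_structural_panel

panel, truth = generate_structural_panel(n_per_family=8, seed=1)
print(f"panel: {len(panel)} metabolites from families "
      f"{sorted(set(truth.families.values()))}")

result = detect_clusters(panel, repeats=10, seed=1)
print(f"selected k* = {result.k_star} chemical classes "
      f"(max mean silhouette {result.profile.mean.max():.3f})")

for cid in range(1, result.k_star + 1):
    members = result.members(cid)
    fams = Counter(truth.families[m] for m in members)
    print(f"  class {cid}: {len(members)} metabolites, families {dict(fams)}")

# A class made of a single family means the embedding separated the planted
# chemical structure perfectly; the silhouette profile shows how sharply
# k* = 3 wins over neighbouring k.
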