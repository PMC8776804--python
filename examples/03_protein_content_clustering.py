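"""Protein clusters, content distances, VGCs and core genes.

ORFs are called on each genome, clustered into protein clusters (PCs) via
reciprocal Smith-Waterman hits (e-value <= 1e-4, bitscore >= 50), and the
Dice dissimilarity of PC presence profiles drives a complete-linkage tree.
Cutting at 0.9 yields viral genome clusters (VGCs), the family-level proxy;
silhouette widths say how firmly each genome sits in its VGC.
"""

import phagetax as pt
from phagetax.proteins import protein_clusters
from phagetax.trees import bootstrap_supports, cut_tree, distance_matrix, hierarchical_tree

spec = pt.CommunitySpec(
    seed=5, n_families=2, genera_per_family=2, species_per_genus=1,
    strains_per_species=1, genome_length_range=(20_000, 24_000),
)
community = pt.plant_taxonomy(spec)

proteins = [p for g in community.genomes for p in pt.call_orfs(g, min_aa=100)]
catalog = protein_clusters(proteins, pt.all_vs_all_hits(proteins))
print(f"{len(proteins)} proteins -> {catalog.counts.shape[1]} protein clusters")

dists = distance_matrix(catalog)
tree = bootstrap_supports(catalog, hierarchical_tree(dists), n_replicates=100, seed=0)
print("\ndendrogram (newick, bootstrap supports on internal nodes):")
print(tree.to_newick())

vgc = cut_tree(tree, dists, height=0.9)
print(f"\n{vgc.n_clusters()} VGCs at the 0.9 cut "
      f"(mean silhouette {vgc.mean_silhouette():.3f}):")
for g in sorted(vgc.assignment):
    print(f"  {g:14s} {vgc.assignment[g]}  silhouette {vgc.silhouette[g]:+.3f}")

members = [g.id for g in community.genomes
           if g.truth_labels["family"] == "F1"]
core = pt.core_pcs(catalog, members, family_id="F1")
print(f"\nfamily F1 core: {len(core.core_pcs)} PCs present in all "
      f"{len(members)} members ({core.duplicates_dropped} duplicates dropped)")
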