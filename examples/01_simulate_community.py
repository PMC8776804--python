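"""Generate a small phage community with planted taxonomic structure.

The generator plants four tiers of truth — identical strain-mates, species
diverged within the 70-95% nucleotide band inside each genus, and families
with fully disjoint gene content — so every downstream stage can be checked
against known labels.
"""

import phagetax as pt

spec = pt.CommunitySpec(
    seed=7, n_families=2, genera_per_family=1, species_per_genus=2,
    strains_per_species=2, genome_length_range=(20_000, 25_000),
)
community = pt.plant_taxonomy(spec)

print(f"{len(community.genomes)} genomes planted:")
for g in community.genomes:
    lab = g.truth_labels
    print(f"  {g.id:14s} {len(g):6d} bp  GC {g.gc:.3f}  "
          f"family {lab['family']}  genus {lab['genus']}  species {lab['species']}")

# evolve a fresh strain-level variant by hand: 97% nucleotide identity
parent = community.genomes[0]
child, edits = pt.evolve_genome(parent, 0.97, indel_rate=0.05, seed=1)
print(f"\nevolved {child.id}: edit-list identity {100 * edits.identity():.2f}% "
      f"({len(edits.substitutions)} substitutions, "
      f"{len(edits.insertions)} insertions, {len(edits.deletions)} deletions)")
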