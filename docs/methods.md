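# Methods

This note documents the models, algorithms and design choices behind
phagetax, in the order data flows through the pipeline.

## Intergenomic similarity and taxon demarcation

Two genomes are compared by local alignment blocks; the similarity is

    sim(a, b) = 100 · (id_a + id_b) / (len_a + len_b),

with `id_x` the number of identical alignment positions on genome `x`
after merging overlapping blocks.  The formula is symmetric, lives in
[0, 100], and penalises unaligned sequence, which is what makes the
95 % / 70 % species/genus conventions meaningful for phage genomes whose
homology is often partial.  Overlap between blocks is resolved exactly
when blocks carry per-position match masks (the internal aligner always
provides them): each genome position counts at most once, as the union of
matched positions.  Count-only blocks ingested from 12-column BLAST
tabular files are consumed best-block-first (by identical positions, ties
by query then subject start) with overlaps truncated and identity
pro-rated over the clipped span.

The internal aligner seeds on exact 13-mers (k-mers occurring more than 10
times in the subject are skipped as repeats), chains anchors greedily in
query order — an anchor extends the chain with the smallest diagonal
change, allowing per-step drift ≤ 60 bp and gaps ≤ 400 bp, so cumulative
indel drift is unbounded — and aligns each chained region globally with
edlib.  Chain ends are extended by up to 200 bp toward the sequence
boundaries to recover anchor-free (e.g. repeat-masked) block ends.  Blocks
are kept when they contain ≥ 30 identical positions at ≥ 65 % identity and
derive from ≥ 2 anchors (or a ≥ 26 bp span); random 10 kb sequence pairs
produce no blocks under these filters, because an optimal global alignment
of unrelated DNA plateaus near 55 % matched columns.

Demarcation applies single-linkage connected components to the graph with
edges where sim ≥ threshold, at 100 / 95 / 70 % for strains / species /
genera.  Equality with the 100 % strain threshold is tested within
ε = 0.01 percentage points (configurable) to absorb floating point; we
read the strain tier as "identical up to measurement", not as a literal
string comparison.  Because raising the threshold only removes edges,
higher-tier partitions always refine lower-tier ones; `demarcate_taxa`
asserts this.

Identity measured by an optimal alignment is a lower-bounded estimator of
positional identity: on substitution-only planted pairs the engine can
only find *at least* as many matched positions as the planted diagonal
(about +0.2 pp at 95 % identity, up to +1.5 pp at 85 %).  Tests therefore
check the similarity formula against the edit-list oracle on constructed
single blocks (exact), and the engine against the oracle with a
divergence-dependent slack.

## Protein clusters, genome content distance, VGCs

ORF calling reports all maximal open reading frames on both strands
(ATG/GTG/TTG starts, standard code, stop required), with 0-based
half-open forward-strand coordinates.  The library default floor is 30
residues; the *pipeline* default is 100 residues (the classic long-ORF
convention).  The higher floor matters because naive six-frame calling on
gene-dense genomes produces many short spurious ORFs (reverse-strand
shadows and nested starts) that dilute presence/absence profiles; planted
genes (and most real phage genes) are comfortably longer.

The all-vs-all protein search is Smith–Waterman with BLOSUM62, gap open
11 / extend 1 (Biopython's PairwiseAligner).  Raw scores are converted
with ungapped Karlin–Altschul constants (λ = 0.3176, K = 0.134):
bits = (λS − ln K)/ln 2 and E = m·n·2^(−bits) for sequence lengths m, n.
An undirected edge is kept only when both directions pass E ≤ 1e-4 and
bits ≥ 50.  Two speedups that do not change semantics materially:
identical sequences are deduplicated behind one representative, and pairs
sharing no exact 5-mer are skipped (word seeding in the BLAST tradition;
a pair with no shared 5-mer essentially cannot reach 50 bits).  For exact
BLASTP statistics, precomputed tabular hits can be ingested instead; that
path enforces reciprocity explicitly.

Protein clusters (PCs) are connected components of the hit graph —
deterministic and parameter-free; cluster ids are the lexicographically
smallest member id.  Genome distance is Sørensen–Dice on PC
presence/absence, d = 1 − 2|A∩B|/(|A|+|B|): a semimetric on [0, 1]
(symmetry and d(a,a)=0 hold; the triangle inequality is not asserted).

Trees are complete-linkage, built in-package so the tie-break is fixed
(merge the pair whose cluster representatives are lexicographically
smallest); complete linkage is monotone, so merge heights are
non-decreasing and live in [0, 1].  Scipy reproduces the same heights on
distinct distances and serves as the oracle in tests.  Bootstrap supports
resample PC columns with replacement (1000 replicates by default; 200 in
the desk-scale pipeline runs), rebuild the tree per replicate, and score
each internal node by the fraction of replicates containing its leaf set;
supports are plain bootstrap proportions — selective-inference or
approximately-unbiased corrections are out of scope.

Viral genome clusters (VGCs) are the maximal subtrees merging below the
cut height (default 0.9), the family-level proxy.  Silhouette widths
s = (b − a)/max(a, b) use the same distance matrix; singletons score 0 by
convention (scikit-learn's convention too, cross-checked in tests).
Core gene sets for a family are the PCs present in every member genome;
when a genome contributes several proteins to a core PC only the longest
is kept as representative, and the number of dropped duplicates is
reported.

## Bloom detection

Per-read identity is (aligned bases − edit distance)/aligned bases with
the edit distance including indels (SAM NM semantics; reconstructed from
MD + CIGAR when NM is absent, and from residue matches / block length for
PAF).  Coverage breadth at a threshold is the fraction of genome positions
overlapped by ≥ 1 qualifying alignment — an interval union, so depth never
inflates breadth; secondary/supplementary alignments are excluded by
default.  Identity filtering is per read, then breadth (the alternative —
a per-base pileup identity — would need base-level alignment detail that
tabular formats do not carry).

The presence rules are strict inequalities exactly as stated above
(bacterium >60 % @ ≥95 %, phage >75 % @ ≥90 %, relative >60 % @ ≥70 %),
so a genome covered exactly 60 % is absent, and a phage can be absent at
species level while its relatives rule fires.  Normalized abundance is
qualifying aligned bases / genome length (bp) / library size (Gb), with
the library size the total read bases before alignment — the only
self-consistent reading.  Phage/host ratios are reported as integers when
≥ 10 and with two decimals below, and an undetected host yields an
explicit undefined value rather than infinity.

## Synthetic communities

`CommunitySpec` defaults plant 3 families × 2 genera × 2 species ×
2 strains (24 genomes of 35–45 kb at GC 0.34, matching the genome sizes
and low GC typical of flavophages).  Construction:

* **Families** are independent random gene-dense ancestors: genes of
  450–1200 bp (ATG + non-stop codons + TAA) separated by 27–57 bp spacers
  that begin with stop codons in all three forward frames.  Independent
  ancestors give fully disjoint gene content across families, emulating
  how candidate phage families share essentially no protein clusters.
* **Genera and species** evolve from the family ancestor with per-branch
  divergences chosen so that cross-species pairs within a genus land
  mid-band in the genus ANI range (sampled per genus from the central part
  of 0.70–0.95) and cross-genus pairs fall to ≈ 0.60 identity, safely
  below the 70 % genus threshold.  Inside `plant_taxonomy` substitutions
  in genes prefer synonymous third-position changes (75 % of the time)
  and never create in-frame stops or touch start/stop codons, and indels
  are confined to intergenic spacers: nucleotide identity decays to genus
  level while proteins stay alignably homologous (≈ 70 % amino-acid
  identity), exactly the regime real phage families occupy.  The generic
  `evolve_genome` operation keeps the simple uniform model: substitutions
  uniform without replacement, indel events Poisson-thinned at
  `indel_rate` × substitutions with geometric lengths capped at 10 bp,
  and a recorded edit list whose positional identity is the planting
  oracle (|realized − target| ≤ 0.5 pp guaranteed by construction).
* **Strains**: isolates of one species are identical sequences sharing a
  strain label — the situation behind "several isolates, one strain" tallies
  in isolation studies.  Consequently the planted strain partition equals
  the species partition; strain-tier *diversity* (95–100 % ANI) is
  exercised in tests by calling `evolve_genome` directly.

Reads are sampled with per-genome probability ∝ weight × length, uniform
start positions, reverse-complement strand with probability 0.5, and
independent per-base substitutions at the requested divergence — no indel
or quality-profile sequencing errors, no GC bias.  Spacers are sampled
intervals with planned substitutions and deletions (gaps), reverse
complemented half the time.

What passing the planted-community tests shows — and does not show: the
pipeline recovers clean, well-separated planted structure exactly; real
communities add mosaicism, recombination, repeat content and uneven
evolutionary rates that the generator deliberately omits, so thresholds
should be read as conventions being implemented faithfully, not as
validated universal cut-offs.

## Problem sizes and numerical choices

Desk-scale runs use 24 genomes of ~40 kb, ~1300 called proteins, 200
bootstrap replicates, and read sets of ≤ 20× coverage at 500 bp — each
full pipeline pass takes well under a minute on one core.  Presence-rule
simulations use 500 bp reads at 20× ("high") and 0.2× ("low") depth: at
that read length the binomial spread of per-read identity keeps the 8 %
divergence tier clear of the 95 % identity threshold, so the expected
truth table is deterministic in practice.  Degenerate inputs are handled
explicitly: empty protein sets fall back to zero content-distance;
genomes absent from an alignment set get breadth 0; an all-identical
distance matrix collapses at height 0.

## Known limitations

* The similarity engine is a desk-scale seeded aligner, not BLASTN; for
  publication-grade numbers on real data use the BLAST-tabular interop
  path.
* Protein clustering is single-step connected components; no MCL-style
  inflation, no HMM superclustering.
* Presence calling consumes alignments; read mapping itself is out of
  scope, as are assembly, annotation, and core-gene phylogeny beyond core
  set extraction.
* Spacer matching is word-seeded: a locus with no exact 10-mer anchor is
  undetectable (irrelevant under the ≤ 1-mismatch assignment rule), and
  constraint filtering applies to the optimal alignment of each candidate
  locus, not to every suboptimal alignment of it.
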