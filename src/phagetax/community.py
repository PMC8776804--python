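"""Synthetic phage/host community generator with planted ground truth.

Every downstream stage of the package (intergenomic-similarity demarcation,
protein-content clustering, read-mapping presence calls, CRISPR spacer
matching) can be exercised offline on communities produced here.  The
generator plants a four-tier taxonomy:

* families — built from independent random ancestors, so genomes from
  different families share no gene sequences at all (their protein-cluster
  content is disjoint);
* genera within a family — ancestors diverged far enough that nucleotide
  similarity falls below the 70% genus demarcation threshold while protein
  sequences stay recognisably homologous (substitutions inside genes prefer
  synonymous third-codon positions);
* species within a genus — diverged so that pairwise nucleotide similarity
  lands inside the genus band (70–95%);
* strains — isolates of the same species are identical sequences, mirroring
  the common situation where several independent phage isolates turn out to
  be the same strain at the 100% similarity threshold.

All randomness flows through a single integer seed per operation; no global
state is used.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .genome import Genome, reverse_complement

_BASES = np.array(list("ACGT"))
_STOPS = {"TAA", "TAG", "TGA"}
_STARTS = {"ATG", "GTG", "TTG"}
# translation table for synonymous-substitution decisions (standard code)
_CODON_TABLE: dict[str, str] = {}
_AA = (
    "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
)
for _i, (_a, _b, _c) in enumerate(itertools.product("TCAG", repeat=3)):
    _CODON_TABLE[_a + _b + _c] = _AA[_i]

# ---------------------------------------------------------------------------
# specs and truth containers


@dataclass(frozen=True)
class CommunitySpec:
    """Parameters of a planted community.

    ANI ranges are fractions in [0, 1].  ``species_ani_range`` must reach
    1.0 because strain-mates (isolates of one species) are generated as
    identical sequences; ``genus_ani_range`` is the band targeted for
    cross-species pairs within a genus.
    """

    seed: int = 0
    n_families: int = 3
    genera_per_family: int = 2
    species_per_genus: int = 2
    strains_per_species: int = 2
    genome_length_range: tuple[int, int] = (35_000, 45_000)
    gc_content: float = 0.34
    species_ani_range: tuple[float, float] = (0.95, 1.0)
    genus_ani_range: tuple[float, float] = (0.70, 0.95)
    indel_rate: float = 0.05
    gene_length_range: tuple[int, int] = (450, 1200)

    def __post_init__(self) -> None:
        for name in ("n_families", "genera_per_family", "species_per_genus",
                     "strains_per_species"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for rng_name in ("species_ani_range", "genus_ani_range"):
            lo, hi = getattr(self, rng_name)
            if not (0.0 <= lo <= hi <= 1.0):
                raise ValueError(f"{rng_name} must be ordered and within [0, 1]")
        if self.species_ani_range[0] < 0.95:
            raise ValueError("species_ani_range must lie at or above 0.95")
        if self.species_ani_range[0] < self.genus_ani_range[1]:
            raise ValueError("species ANI range must lie strictly above the genus range")
        if self.species_ani_range[1] < 1.0:
            raise ValueError(
                "species_ani_range must reach 1.0: strain-mates are identical sequences"
            )
        if not (0.0 < self.gc_content < 1.0):
            raise ValueError("gc_content must be in (0, 1)")
        if self.genome_length_range[0] < 1000 or (
            self.genome_length_range[0] > self.genome_length_range[1]
        ):
            raise ValueError("genome_length_range must be ordered and >= 1000 bp")
        if self.indel_rate < 0:
            raise ValueError("indel_rate must be >= 0")


@dataclass(frozen=True)
class EditList:
    """Planted edits of one evolution step, in parent coordinates.

    ``substitutions`` are (position, old_base, new_base); ``insertions`` are
    (position, inserted_sequence) meaning the sequence is inserted before
    that parent position; ``deletions`` are (position, length).
    """

    parent_length: int
    substitutions: tuple[tuple[int, str, str], ...]
    insertions: tuple[tuple[int, str], ...]
    deletions: tuple[tuple[int, int], ...]

    def identity(self) -> float:
        """Position-wise identity oracle on the aligned (non-indel) columns.

        Deleted parent positions and inserted child positions are gap
        columns and do not count as aligned; every surviving position is
        aligned, and is identical unless substituted.
        """
        aligned = self.parent_length - sum(ln for _, ln in self.deletions)
        return (aligned - len(self.substitutions)) / aligned


@dataclass
class Read:
    id: str
    sequence: str
    origin_id: str
    start: int  # 0-based half-open interval on the origin genome (forward strand)
    end: int
    strand: str
    n_substitutions: int = 0


@dataclass
class ReadSet:
    reads: list[Read]
    library_size_gb: float

    @property
    def total_bases(self) -> int:
        return sum(len(r.sequence) for r in self.reads)


@dataclass(frozen=True)
class SpacerTruth:
    spacer_id: str
    sequence: str
    source_id: str
    start: int  # genome interval the spacer derives from (includes gap bases)
    end: int
    strand: str
    n_substitutions: int
    gap_lengths: tuple[int, ...]


@dataclass
class CrisprTruth:
    spacers: list[SpacerTruth]


@dataclass
class PlantedCommunity:
    spec: CommunitySpec
    genomes: list[Genome]
    gene_intervals: dict[str, list[tuple[int, int]]]
    family_gene_sequences: dict[str, list[str]]

    def truth_partition(self, level: str) -> dict[str, str]:
        return {g.id: g.truth_labels[level] for g in self.genomes}


# ---------------------------------------------------------------------------
# ancestors and evolution


def generate_ancestor(length: int, gc: float, seed: int) -> Genome:
    """Random genome with the requested GC content (deterministic per seed)."""
    if length < 1000:
        raise ValueError("ancestor length must be >= 1000 bp")
    if not (0.0 < gc < 1.0):
        raise ValueError("gc must be in (0, 1)")
    rng = np.random.default_rng(seed)
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    seq = "".join(rng.choice(_BASES, size=length, p=probs))
    return Genome(id=f"anc_{seed}", sequence=seq)


def _place_indels(
    rng: np.random.Generator,
    length: int,
    n_events: int,
    allowed: tuple[int, int] | None = None,
) -> tuple[list[tuple[int, str]], list[tuple[int, int]]]:
    """Sample non-overlapping insertion/deletion events (geometric lengths, cap 10)."""
    insertions: list[tuple[int, str]] = []
    deletions: list[tuple[int, int]] = []
    occupied: set[int] = set()
    lo, hi = (0, length) if allowed is None else allowed
    for _ in range(n_events):
        ln = int(min(rng.geometric(0.5), 10))
        for _attempt in range(50):
            pos = int(rng.integers(lo, max(lo + 1, hi - ln)))
            span = range(pos, pos + ln)
            if not occupied.intersection(span):
                occupied.update(span)
                if rng.random() < 0.5:
                    insertions.append((pos, "".join(rng.choice(_BASES, size=ln))))
                else:
                    deletions.append((pos, ln))
                break
    return insertions, deletions


def _apply_edits(parent: str, edits: EditList) -> str:
    sub_at = {p: new for p, _, new in edits.substitutions}
    ins_at: dict[int, str] = {}
    for p, s in edits.insertions:
        ins_at[p] = ins_at.get(p, "") + s
    deleted = np.zeros(len(parent), dtype=bool)
    for p, ln in edits.deletions:
        deleted[p : p + ln] = True
    out: list[str] = []
    for i, base in enumerate(parent):
        if i in ins_at:
            out.append(ins_at[i])
        if deleted[i]:
            continue
        out.append(sub_at.get(i, base))
    if len(parent) in ins_at:
        out.append(ins_at[len(parent)])
    return "".join(out)


def evolve_genome(
    parent: Genome,
    target_identity: float,
    indel_rate: float = 0.0,
    seed: int = 0,
    child_id: str | None = None,
) -> tuple[Genome, EditList]:
    """Derive a child genome at a controlled nucleotide identity.

    Substitutions are placed uniformly at random without replacement;
    insertion/deletion events are Poisson-thinned at ``indel_rate`` events
    per substitution with geometric lengths capped at 10 bp.  The returned
    :class:`EditList` is the planted truth; its :meth:`EditList.identity`
    equals the target up to rounding of the substitution count.
    """
    if not (0.0 < target_identity <= 1.0):
        raise ValueError("target_identity must be in (0, 1]")
    cid = child_id or f"{parent.id}_child{seed}"
    if target_identity == 1.0:
        return (
            Genome(cid, parent.sequence, truth_labels=dict(parent.truth_labels or {})),
            EditList(len(parent), (), (), ()),
        )
    rng = np.random.default_rng(seed)
    L = len(parent)
    approx_subs = (1.0 - target_identity) * L
    n_events = int(rng.poisson(indel_rate * approx_subs)) if indel_rate > 0 else 0
    insertions, deletions = _place_indels(rng, L, n_events)
    deleted = np.zeros(L, dtype=bool)
    for p, ln in deletions:
        deleted[p : p + ln] = True
    surviving = np.flatnonzero(~deleted)
    n_subs = int(round((1.0 - target_identity) * surviving.size))
    sub_pos = rng.choice(surviving, size=n_subs, replace=False)
    subs = []
    for p in sorted(int(x) for x in sub_pos):
        old = parent.sequence[p]
        choices = [b for b in "ACGT" if b != old]
        subs.append((p, old, choices[int(rng.integers(0, 3))]))
    edits = EditList(L, tuple(subs), tuple(insertions), tuple(deletions))
    return Genome(cid, _apply_edits(parent.sequence, edits)), edits


def oracle_alignment_block(parent: Genome, child: Genome, edits: EditList):
    """The exact full-length alignment block implied by a substitution-only
    edit list — the position-wise oracle against which the seeded aligner
    and the similarity formula are validated."""
    from .pairwise import AlignmentBlock

    if edits.insertions or edits.deletions:
        raise ValueError("oracle block construction requires a substitution-only edit list")
    L = edits.parent_length
    return AlignmentBlock(
        parent.id, child.id, (0, L), (0, L), "+",
        L - len(edits.substitutions), L,
    )


# ---------------------------------------------------------------------------
# gene-structured ancestors and codon-aware evolution (taxonomy planting)

_SPACER_STOP_PREFIX = "TTAATTAATTAA"  # stop codons in all three forward frames


def _random_gene(rng: np.random.Generator, length_nt: int, gc: float) -> str:
    """ATG + non-stop codons + TAA; length rounded down to a codon multiple."""
    n_codons = max(length_nt // 3, 12)
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    body: list[str] = []
    while len(body) < n_codons - 2:
        cod = "".join(rng.choice(_BASES, size=3, p=probs))
        if cod not in _STOPS:
            body.append(cod)
    return "ATG" + "".join(body) + "TAA"


def _build_family_ancestor(
    rng: np.random.Generator, spec: CommunitySpec
) -> tuple[str, list[tuple[int, int]], list[str]]:
    target_len = int(rng.integers(spec.genome_length_range[0],
                                  spec.genome_length_range[1] + 1))
    parts: list[str] = []
    genes: list[tuple[int, int]] = []
    gene_seqs: list[str] = []
    pos = 0
    lo, hi = spec.gene_length_range
    probs = [(1 - spec.gc_content) / 2, spec.gc_content / 2,
             spec.gc_content / 2, (1 - spec.gc_content) / 2]
    while pos < target_len:
        spacer = _SPACER_STOP_PREFIX + "".join(
            rng.choice(_BASES, size=int(rng.integers(15, 45)), p=probs)
        )
        parts.append(spacer)
        pos += len(spacer)
        gene = _random_gene(rng, int(rng.integers(lo, hi + 1)), spec.gc_content)
        genes.append((pos, pos + len(gene)))
        gene_seqs.append(gene)
        parts.append(gene)
        pos += len(gene)
    return "".join(parts), genes, gene_seqs


def _synonymous_choices(codon: str, offset: int) -> list[str]:
    aa = _CODON_TABLE[codon]
    out = []
    for b in "ACGT":
        if b == codon[offset]:
            continue
        alt = codon[:offset] + b + codon[offset + 1 :]
        if _CODON_TABLE[alt] == aa:
            out.append(b)
    return out


def _nonstop_choices(codon: str, offset: int) -> list[str]:
    out = []
    for b in "ACGT":
        if b == codon[offset]:
            continue
        alt = codon[:offset] + b + codon[offset + 1 :]
        if alt not in _STOPS:
            out.append(b)
    return out


def _evolve_with_genes(
    seq: str,
    genes: list[tuple[int, int]],
    divergence: float,
    indel_rate: float,
    rng: np.random.Generator,
    syn_bias: float = 0.75,
) -> tuple[str, list[tuple[int, int]]]:
    """Evolve a gene-structured sequence by ``divergence`` substitutions/site.

    Indels are confined to intergenic spacers so reading frames survive;
    in-gene substitutions prefer synonymous third-position changes with
    probability ``syn_bias`` and never create in-frame stop codons or touch
    start/stop codons, which keeps protein content homologous across deep
    (genus-level) nucleotide divergence.
    """
    L = len(seq)
    in_gene = np.full(L, -1, dtype=np.int64)  # index of containing gene
    protected = np.zeros(L, dtype=bool)
    for gi, (s, e) in enumerate(genes):
        in_gene[s:e] = gi
        protected[s : s + 3] = True
        protected[e - 3 : e] = True

    # --- indels in intergenic regions only
    approx_subs = divergence * L
    n_events = int(rng.poisson(indel_rate * approx_subs)) if indel_rate > 0 else 0
    intergenic = np.flatnonzero(in_gene < 0)
    insertions: list[tuple[int, str]] = []
    deletions: list[tuple[int, int]] = []
    occupied: set[int] = set()
    for _ in range(n_events):
        ln = int(min(rng.geometric(0.5), 10))
        for _attempt in range(50):
            pos = int(intergenic[rng.integers(0, intergenic.size)])
            span = set(range(pos, pos + ln))
            if span.issubset(set(intergenic.tolist())) and not span & occupied:
                occupied |= span
                if rng.random() < 0.5:
                    insertions.append((pos, "".join(rng.choice(_BASES, size=ln))))
                else:
                    deletions.append((pos, ln))
                break

    deleted = np.zeros(L, dtype=bool)
    for p, ln in deletions:
        deleted[p : p + ln] = True

    # --- substitutions
    eligible = np.flatnonzero(~deleted & ~protected)
    n_subs = int(round(divergence * (L - deleted.sum())))
    n_subs = min(n_subs, eligible.size)
    chosen = rng.choice(eligible, size=n_subs, replace=False)
    sub_at: dict[int, str] = {}
    for p in (int(x) for x in chosen):
        gi = in_gene[p]
        if gi < 0:
            old = seq[p]
            alts = [b for b in "ACGT" if b != old]
            sub_at[p] = alts[int(rng.integers(0, len(alts)))]
            continue
        gs = genes[gi][0]
        off = (p - gs) % 3
        cstart = p - off
        codon = seq[cstart : cstart + 3]
        syn = _synonymous_choices(codon, off)
        if syn and rng.random() < syn_bias:
            sub_at[p] = syn[int(rng.integers(0, len(syn)))]
        else:
            alts = _nonstop_choices(codon, off)
            if not alts:
                continue
            sub_at[p] = alts[int(rng.integers(0, len(alts)))]

    edits = EditList(
        L,
        tuple((p, seq[p], b) for p, b in sorted(sub_at.items())),
        tuple(insertions),
        tuple(deletions),
    )
    child = _apply_edits(seq, edits)

    # --- shift gene coordinates through the (intergenic) indels
    events = [(p, len(s)) for p, s in insertions] + [(p, -ln) for p, ln in deletions]
    events.sort()
    new_genes: list[tuple[int, int]] = []
    for s, e in genes:
        shift = sum(d for p, d in events if p < s)
        new_genes.append((s + shift, e + shift))
    return child, new_genes


def plant_taxonomy(spec: CommunitySpec) -> PlantedCommunity:
    """Generate a community with planted strain/species/genus/family structure."""
    rng = np.random.default_rng(spec.seed)
    g_lo, g_hi = spec.genus_ani_range
    span = g_hi - g_lo
    # cross-genus (same family) nucleotide identity target: safely below the
    # genus band so the 70% demarcation separates genera
    cross_genus_ani = min(0.60, g_lo - 0.08)

    genomes: list[Genome] = []
    gene_map: dict[str, list[tuple[int, int]]] = {}
    family_genes: dict[str, list[str]] = {}
    for fi in range(spec.n_families):
        fam = f"F{fi + 1}"
        anc_seq, anc_genes, anc_gene_seqs = _build_family_ancestor(rng, spec)
        family_genes[fam] = anc_gene_seqs
        for gi in range(spec.genera_per_family):
            genus = f"{fam}G{gi + 1}"
            # within-genus cross-species ANI target, sampled mid-band
            t_genus = float(rng.uniform(g_lo + 0.30 * span, g_hi - 0.35 * span))
            d_species = (1.0 - t_genus) / 2.0
            d_genus = max(0.02, (1.0 - cross_genus_ani) / 2.0 - d_species)
            gseq, ggenes = _evolve_with_genes(
                anc_seq, anc_genes, d_genus, spec.indel_rate, rng
            )
            for si in range(spec.species_per_genus):
                species = f"{genus}S{si + 1}"
                sseq, sgenes = _evolve_with_genes(
                    gseq, ggenes, d_species, spec.indel_rate, rng
                )
                strain = f"{species}ST1"
                for ii in range(spec.strains_per_species):
                    gid = f"{species}_i{ii + 1}"
                    genomes.append(
                        Genome(
                            gid,
                            sseq,
                            truth_labels={
                                "strain": strain,
                                "species": species,
                                "genus": genus,
                                "family": fam,
                            },
                        )
                    )
                    gene_map[gid] = list(sgenes)
    return PlantedCommunity(spec, genomes, gene_map, family_genes)


# ---------------------------------------------------------------------------
# reads


def simulate_reads(
    genomes: Sequence[Genome],
    abundances: Mapping[str, float],
    read_length: int,
    per_base_divergence: float,
    total_bases: int,
    seed: int = 0,
) -> ReadSet:
    """Sample reads with per-genome weights proportional to weight x length.

    Read start positions are uniform, strands are assigned reverse-complement
    with probability 0.5, and each base mutates independently at
    ``per_base_divergence`` (uniform error profile, no indels).
    """
    if not genomes:
        raise ValueError("empty genome collection")
    if not (0.0 <= per_base_divergence < 1.0):
        raise ValueError("per_base_divergence must be in [0, 1)")
    weights = np.array([float(abundances.get(g.id, 0.0)) for g in genomes])
    if (weights < 0).any() or weights.sum() <= 0:
        raise ValueError("abundance weights must be >= 0 and sum to > 0")
    active = [g for g, w in zip(genomes, weights) if w > 0]
    if read_length > min(len(g) for g in active):
        raise ValueError("read_length exceeds the shortest weighted genome")
    rng = np.random.default_rng(seed)
    lengths = np.array([len(g) for g in genomes], dtype=float)
    p = weights * lengths
    p /= p.sum()
    n_reads = int(round(total_bases / read_length))
    counts = rng.multinomial(n_reads, p)
    reads: list[Read] = []
    k = 0
    for g, c in zip(genomes, counts):
        if c == 0:
            continue
        L = len(g)
        starts = rng.integers(0, L - read_length + 1, size=c)
        strands = rng.random(c) < 0.5
        n_subs = rng.binomial(read_length, per_base_divergence, size=c)
        for start, minus, ns in zip(starts, strands, n_subs):
            start = int(start)
            frag = list(g.sequence[start : start + read_length])
            for pos in rng.choice(read_length, size=int(ns), replace=False):
                old = frag[pos]
                alts = [b for b in "ACGT" if b != old]
                frag[pos] = alts[int(rng.integers(0, 3))]
            seq = "".join(frag)
            strand = "-" if minus else "+"
            if minus:
                seq = reverse_complement(seq)
            reads.append(
                Read(f"read_{k}", seq, g.id, start, start + read_length, strand, int(ns))
            )
            k += 1
    return ReadSet(reads, library_size_gb=sum(len(r.sequence) for r in reads) / 1e9)


def write_fastq(readset: ReadSet, path: str | Path, quality_char: str = "I") -> None:
    with open(path, "w") as fh:
        for r in readset.reads:
            fh.write(f"@{r.id}\n{r.sequence}\n+\n{quality_char * len(r.sequence)}\n")


# ---------------------------------------------------------------------------
# CRISPR spacers


def plant_spacers(
    phage: Genome,
    n: int,
    lengths: tuple[int, int] = (25, 45),
    edits: Sequence[tuple[int, tuple[int, ...]]] | None = None,
    seed: int = 0,
) -> CrisprTruth:
    """Sample spacers from a phage genome with a planted edit plan.

    ``edits`` lists, per spacer, (substitution count, gap lengths); gaps are
    deletions relative to the phage (the spacer skips those genome bases).
    The plan is cycled if shorter than ``n``.  Spacers are reverse
    complemented with probability 0.5.
    """
    if n <= 0:
        raise ValueError("n must be > 0")
    lo, hi = lengths
    if not (20 <= lo <= hi <= 60):
        raise ValueError("spacer lengths must lie within [20, 60]")
    plan = list(edits) if edits else [(0, ())]
    rng = np.random.default_rng(seed)
    out: list[SpacerTruth] = []
    for i in range(n):
        n_sub, gaps = plan[i % len(plan)]
        gaps = tuple(int(g) for g in gaps)
        slen = int(rng.integers(lo, hi + 1))
        span = slen + sum(gaps)
        start = int(rng.integers(0, len(phage) - span + 1))
        frag = phage.sequence[start : start + span]
        # carve out gap segments between equal-length kept blocks so every
        # gap sits at an interior offset
        kept = frag
        if gaps:
            seg = slen // (len(gaps) + 1)
            pieces = []
            cursor = 0
            for g in gaps:
                pieces.append(frag[cursor : cursor + seg])
                cursor += seg + g
            pieces.append(frag[cursor:])
            kept = "".join(pieces)[:slen]
        seq = list(kept)
        if n_sub > 0:
            for pos in rng.choice(len(seq), size=min(n_sub, len(seq)), replace=False):
                old = seq[pos]
                alts = [b for b in "ACGT" if b != old]
                seq[pos] = alts[int(rng.integers(0, 3))]
        spacer = "".join(seq)
        strand = "+"
        if rng.random() < 0.5:
            spacer = reverse_complement(spacer)
            strand = "-"
        out.append(
            SpacerTruth(
                f"{phage.id}_sp{i + 1}", spacer, phage.id, start, start + span,
                strand, int(min(n_sub, slen)), gaps,
            )
        )
    return CrisprTruth(out)
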