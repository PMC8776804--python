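"""Proteomes, all-vs-all protein similarity, and protein clusters (PCs).

Proteins are either supplied as amino-acid FASTA (header convention
``genomeID|proteinID``) or called internally as maximal ORFs.  The all-vs-all
search is a Smith-Waterman alignment (BLOSUM62, gap open 11 / extend 1)
whose raw score S is converted to a bitscore with ungapped Karlin-Altschul
constants,

    bits = (lambda * S - ln K) / ln 2,     E = m * n * 2^(-bits),

and an edge between two proteins is kept only when both directional hits
satisfy E <= 1e-4 and bitscore >= 50.  Protein clusters are the connected
components of that reciprocal-hit graph.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq

from .genome import Genome, reverse_complement

# ungapped Karlin-Altschul constants for BLOSUM62
KA_LAMBDA = 0.3176
KA_K = 0.134
EVALUE_MAX = 1e-4
BITSCORE_MIN = 50.0

_START_CODONS = {"ATG", "GTG", "TTG"}
_STOP_CODONS = {"TAA", "TAG", "TGA"}


@dataclass(frozen=True)
class ProteinRecord:
    protein_id: str
    genome_id: str
    sequence: str
    start: int | None = None  # 0-based half-open on the forward strand
    end: int | None = None
    strand: str | None = None


@dataclass
class HitGraph:
    """Undirected reciprocal-hit graph over protein ids."""

    nodes: list[str]
    edges: dict[tuple[str, str], tuple[float, float]]  # (evalue, bitscore) of best pair

    def neighbors(self, pid: str) -> list[str]:
        out = []
        for a, b in self.edges:
            if a == pid:
                out.append(b)
            elif b == pid:
                out.append(a)
        return out


@dataclass
class PCCatalog:
    """Protein-cluster membership plus the genome x PC count matrix."""

    pc_of: dict[str, str]
    counts: pd.DataFrame  # genomes x PCs, integer counts
    records: dict[str, ProteinRecord]

    @property
    def genomes(self) -> list[str]:
        return list(self.counts.index)

    def pcs_of_genome(self, genome_id: str) -> set[str]:
        if genome_id not in self.counts.index:
            raise ValueError(f"unknown genome id {genome_id!r}")
        row = self.counts.loc[genome_id]
        return set(row.index[row > 0])


@dataclass
class CoreSet:
    family_id: str
    core_pcs: list[str]
    representatives: dict[str, dict[str, str]]  # pc -> genome -> protein id (longest)
    duplicates_dropped: int


# ---------------------------------------------------------------------------
# ORF calling


def call_orfs(genome: Genome, min_aa: int = 30) -> list[ProteinRecord]:
    """All maximal ORFs of >= ``min_aa`` residues on both strands.

    Maximal means: in each frame, an ORF runs from the first start codon
    (ATG/GTG/TTG) after the previous stop to the next in-frame stop codon.
    Coordinates are 0-based half-open on the forward strand; ORFs without a
    terminating stop codon are not reported.
    """
    records: list[ProteinRecord] = []
    L = len(genome)
    for strand, seq in (("+", genome.sequence), ("-", reverse_complement(genome.sequence))):
        for frame in range(3):
            start: int | None = None
            for pos in range(frame, len(seq) - 2, 3):
                codon = seq[pos : pos + 3]
                if codon in _STOP_CODONS:
                    if start is not None and (pos - start) // 3 >= min_aa:
                        aa = str(Seq(seq[start:pos]).translate(table=11))
                        if strand == "+":
                            s, e = start, pos + 3
                        else:
                            s, e = L - (pos + 3), L - start
                        records.append(
                            ProteinRecord("", genome.id, aa, s, e, strand)
                        )
                    start = None
                elif start is None and codon in _START_CODONS:
                    start = pos
    records.sort(key=lambda r: (r.start, r.end, r.strand))
    return [
        ProteinRecord(f"{genome.id}|p{i + 1:04d}", r.genome_id, r.sequence,
                      r.start, r.end, r.strand)
        for i, r in enumerate(records)
    ]


# ---------------------------------------------------------------------------
# all-vs-all protein hits


def _make_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner(mode="local", open_gap_score=-11.0, extend_gap_score=-1.0)
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    return aligner


def bitscore(raw_score: float) -> float:
    return (KA_LAMBDA * raw_score - np.log(KA_K)) / np.log(2.0)


def evalue(raw_score: float, m: int, n: int) -> float:
    return float(m) * float(n) * 2.0 ** (-bitscore(raw_score))


def _seed_words(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def all_vs_all_hits(
    proteins: Sequence[ProteinRecord],
    evalue_max: float = EVALUE_MAX,
    bitscore_min: float = BITSCORE_MIN,
    seed_prefilter: bool = True,
    seed_k: int = 5,
) -> HitGraph:
    """Reciprocal Smith-Waterman hit graph with e-value/bitscore filtering.

    ``seed_prefilter`` skips pairs that share no exact ``seed_k``-mer
    (word-based seeding in the BLAST tradition); identical sequences are
    deduplicated before alignment and their edges expanded afterwards.
    Self-hits are never reported.
    """
    if not proteins:
        raise ValueError("empty protein collection")
    ids = [p.protein_id for p in proteins]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate protein ids")
    aligner = _make_aligner()

    # group exact-duplicate sequences behind one representative
    by_seq: dict[str, list[ProteinRecord]] = {}
    for p in proteins:
        by_seq.setdefault(p.sequence, []).append(p)
    reps = [grp[0] for grp in by_seq.values()]
    words = {r.protein_id: _seed_words(r.sequence, seed_k) for r in reps} if seed_prefilter else {}

    def hit(pa: ProteinRecord, pb: ProteinRecord) -> tuple[float, float] | None:
        score = aligner.score(pa.sequence, pb.sequence)
        e = evalue(score, len(pa.sequence), len(pb.sequence))
        b = bitscore(score)
        if e <= evalue_max and b >= bitscore_min:
            return (e, b)
        return None

    edges: dict[tuple[str, str], tuple[float, float]] = {}

    def add_edge(a: str, b: str, val: tuple[float, float]) -> None:
        key = (a, b) if a < b else (b, a)
        if key not in edges or val[1] > edges[key][1]:
            edges[key] = val

    # duplicate groups: every within-group pair is connected if the self-hit passes
    for seq, grp in by_seq.items():
        if len(grp) > 1:
            val = hit(grp[0], grp[0])
            if val is not None:
                for pa, pb in itertools.combinations(grp, 2):
                    add_edge(pa.protein_id, pb.protein_id, val)

    for ra, rb in itertools.combinations(reps, 2):
        if seed_prefilter and words[ra.protein_id].isdisjoint(words[rb.protein_id]):
            continue
        val = hit(ra, rb)
        if val is None:
            continue
        for pa in by_seq[ra.sequence]:
            for pb in by_seq[rb.sequence]:
                add_edge(pa.protein_id, pb.protein_id, val)

    return HitGraph(list(ids), edges)


def hitgraph_from_tabular(
    proteins: Sequence[ProteinRecord],
    path: str | Path,
    evalue_max: float = EVALUE_MAX,
    bitscore_min: float = BITSCORE_MIN,
) -> HitGraph:
    """Build the reciprocal-hit graph from precomputed 12-column BLASTP output.

    An undirected edge is kept only when hits exist in *both* directions and
    each passes the e-value/bitscore filter.
    """
    df = pd.read_csv(
        path, sep="\t", comment="#",
        names=["qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
               "qstart", "qend", "sstart", "send", "evalue", "bitscore"],
    )
    known = {p.protein_id for p in proteins}
    best: dict[tuple[str, str], tuple[float, float]] = {}
    for row in df.itertuples(index=False):
        q, s = str(row.qseqid), str(row.sseqid)
        if q == s or q not in known or s not in known:
            continue
        e, b = float(row.evalue), float(row.bitscore)
        if e <= evalue_max and b >= bitscore_min:
            if (q, s) not in best or b > best[(q, s)][1]:
                best[(q, s)] = (e, b)
    edges: dict[tuple[str, str], tuple[float, float]] = {}
    for (q, s), (e, b) in best.items():
        if q < s and (s, q) in best:
            e2, b2 = best[(s, q)]
            edges[(q, s)] = (min(e, e2), max(b, b2))
    return HitGraph([p.protein_id for p in proteins], edges)


# ---------------------------------------------------------------------------
# protein clusters


def protein_clusters(
    proteins: Sequence[ProteinRecord], graph: HitGraph
) -> PCCatalog:
    """Connected components of the hit graph; singletons form singleton PCs.

    PC ids are deterministic: the lexicographically smallest member protein id.
    """
    parent: dict[str, str] = {p.protein_id: p.protein_id for p in proteins}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in graph.edges:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)
    members: dict[str, list[str]] = {}
    for p in proteins:
        members.setdefault(find(p.protein_id), []).append(p.protein_id)
    pc_of = {}
    for ms in members.values():
        pc_id = "PC|" + min(ms)
        for m in ms:
            pc_of[m] = pc_id
    recs = {p.protein_id: p for p in proteins}
    genomes = sorted({p.genome_id for p in proteins})
    pcs = sorted(set(pc_of.values()))
    counts = pd.DataFrame(0, index=genomes, columns=pcs, dtype=int)
    for p in proteins:
        counts.loc[p.genome_id, pc_of[p.protein_id]] += 1
    return PCCatalog(pc_of, counts, recs)


def core_pcs(catalog: PCCatalog, members: Sequence[str], family_id: str = "family") -> CoreSet:
    """PCs present in every member genome, with paralog deduplication.

    When a genome contributes more than one protein to a core PC, only the
    longest member is retained as that genome's representative (the number
    of dropped duplicates is reported).
    """
    if len(members) < 2:
        raise ValueError("need at least 2 member genomes")
    for m in members:
        if m not in catalog.counts.index:
            raise ValueError(f"genome {m!r} not in catalog")
    sub = catalog.counts.loc[list(members)]
    core = [pc for pc in sub.columns if (sub[pc] > 0).all()]
    reps: dict[str, dict[str, str]] = {}
    dropped = 0
    by_pc_genome: dict[tuple[str, str], list[ProteinRecord]] = {}
    for pid, pc in catalog.pc_of.items():
        rec = catalog.records[pid]
        if pc in core and rec.genome_id in members:
            by_pc_genome.setdefault((pc, rec.genome_id), []).append(rec)
    for pc in core:
        reps[pc] = {}
        for g in members:
            cands = sorted(
                by_pc_genome.get((pc, g), []),
                key=lambda r: (-len(r.sequence), r.protein_id),
            )
            reps[pc][g] = cands[0].protein_id
            dropped += len(cands) - 1
    return CoreSet(family_id, sorted(core), reps, dropped)


# ---------------------------------------------------------------------------
# proteome FASTA I/O (header convention: genomeID|proteinID)


def read_proteome_fasta(path: str | Path) -> list[ProteinRecord]:
    from Bio import SeqIO

    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if "|" not in rec.id:
            raise ValueError(f"proteome header {rec.id!r} lacks 'genomeID|proteinID'")
        genome_id = rec.id.split("|", 1)[0]
        out.append(ProteinRecord(rec.id, genome_id, str(rec.seq).upper()))
    if not out:
        raise ValueError(f"no proteins found in {path}")
    return out


def write_proteome_fasta(proteins: Iterable[ProteinRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in proteins:
            fh.write(f">{p.protein_id}\n{p.sequence}\n")
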