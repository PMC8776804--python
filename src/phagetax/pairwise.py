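"""Whole-genome intergenomic similarity and taxon demarcation.

Pairs of genomes are compared by a seeded local alignment (exact k-mer
anchors on both strands, chained by diagonal, with the chained region
aligned globally by edlib), and summarised as an intergenomic similarity

    sim(a, b) = 100 * (id_a + id_b) / (len(a) + len(b))

where ``id_x`` counts identical positions on genome ``x`` after merging
overlapping aligned intervals (best block first).  Unaligned sequence counts
as dissimilar, so the measure combines identity and aligned fraction, the
behaviour expected of whole-genome similarity used for phage taxonomy.

Demarcation applies single-linkage connected components at 100 / 95 / 70 %
similarity for strains / species / genera; higher thresholds always refine
lower ones because the edge set only shrinks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import edlib
import numpy as np
import pandas as pd

from .genome import Genome, check_unique_ids, reverse_complement

STRAIN_THRESHOLD = 100.0
SPECIES_THRESHOLD = 95.0
GENUS_THRESHOLD = 70.0
#: tolerance (percentage points) when testing equality with the 100% strain threshold
STRAIN_EPSILON = 0.01


@dataclass(frozen=True)
class AlignmentBlock:
    """One local alignment between two genomes (0-based half-open intervals).

    Blocks produced by the internal aligner also carry per-position match
    masks (forward-strand coordinates), which make the overlap-merged
    identity count exact even across tandem-repeat ambiguities; blocks
    ingested from tabular alignments only carry counts and are pro-rated
    when truncated.
    """

    query_id: str
    subject_id: str
    query_interval: tuple[int, int]
    subject_interval: tuple[int, int]
    strand: str  # '+' or '-'
    identical_positions: float
    aligned_length: int
    query_match: np.ndarray | None = field(default=None, compare=False, repr=False)
    subject_match: np.ndarray | None = field(default=None, compare=False, repr=False)

    def __post_init__(self) -> None:
        if self.identical_positions > self.aligned_length:
            raise ValueError("identical_positions cannot exceed aligned_length")


@dataclass
class SimilarityMatrix:
    ids: list[str]
    values: np.ndarray  # symmetric, percentages in [0, 100], diagonal 100
    aligned_fraction: np.ndarray | None = None

    def __post_init__(self) -> None:
        v = self.values
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape does not match ids")
        if not np.allclose(v, v.T, atol=1e-9):
            raise ValueError("similarity matrix must be symmetric")
        if (v < -1e-9).any() or (v > 100 + 1e-9).any():
            raise ValueError("similarities must lie in [0, 100]")

    def loc(self, a: str, b: str) -> float:
        return float(self.values[self.ids.index(a), self.ids.index(b)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


@dataclass
class TaxonPartition:
    level: str  # strain | species | genus (or free-form)
    assignment: dict[str, str]
    threshold: float

    def clusters(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for gid, cid in self.assignment.items():
            out.setdefault(cid, []).append(gid)
        return {k: sorted(v) for k, v in out.items()}

    def n_clusters(self) -> int:
        return len(set(self.assignment.values()))

    def refines(self, other: "TaxonPartition") -> bool:
        """True if every cluster of this partition fits inside one of ``other``."""
        mine = self.clusters().values()
        return all(len({other.assignment[g] for g in grp}) == 1 for grp in mine)


# ---------------------------------------------------------------------------
# seeded alignment engine


class KmerIndex:
    """Exact k-mer position index of one genome (forward strand)."""

    def __init__(self, genome: Genome, k: int = 13):
        self.k = k
        self.genome = genome
        idx: dict[str, list[int]] = {}
        s = genome.sequence
        for i in range(len(s) - k + 1):
            idx.setdefault(s[i : i + k], []).append(i)
        self.index = idx

    def hits(self, query: str, max_multiplicity: int = 10) -> list[tuple[int, int]]:
        """(query_pos, subject_pos) pairs of exact k-mer matches.

        k-mers occurring more than ``max_multiplicity`` times in the subject
        are skipped (repeat masking for the chaining stage).
        """
        k = self.k
        out: list[tuple[int, int]] = []
        for i in range(len(query) - k + 1):
            pos = self.index.get(query[i : i + k], ())
            if len(pos) > max_multiplicity:
                continue
            for j in pos:
                out.append((i, j))
        return out


def _chain_anchors(
    anchors: list[tuple[int, int]],
    k: int,
    max_diag_drift: int = 60,
    max_gap: int = 400,
) -> list[tuple[int, int, int, int, int]]:
    """Greedy colinear chaining of anchors into candidate regions.

    Anchors are scanned in query order; an anchor extends a chain when it
    advances both coordinates by at most ``max_gap`` and shifts the diagonal
    by at most ``max_diag_drift`` relative to the chain's last anchor (so a
    chain can absorb unbounded cumulative indel drift across a genome).
    Returns (qstart, qend, sstart, send, n_anchors) per chain.
    """
    if not anchors:
        return []
    anchors = sorted(anchors)
    chains: list[list[tuple[int, int]]] = []
    for q, s in anchors:
        best_ch = None
        best_drift = None
        for ch in chains[-50:]:
            lq, ls = ch[-1]
            dq, ds = q - lq, s - ls
            if 0 <= dq <= max_gap and 0 <= ds <= max_gap and abs(dq - ds) <= max_diag_drift:
                drift = abs(dq - ds)
                if best_drift is None or drift < best_drift:
                    best_ch, best_drift = ch, drift
        if best_ch is not None:
            best_ch.append((q, s))
        else:
            chains.append([(q, s)])
    out = []
    for ch in chains:
        qs, ss = ch[0]
        qe = ch[-1][0] + k
        se = max(s for _, s in ch) + k
        out.append((qs, qe, ss, se, len(ch)))
    return out


def _cigar_walk(cigar: str, qlen: int, slen: int) -> tuple[int, int, np.ndarray, np.ndarray]:
    """Walk an extended CIGAR ('='/'X'/'I'/'D'); return identical positions,
    aligned columns, and per-position match masks on query and subject."""
    qmask = np.zeros(qlen, dtype=bool)
    smask = np.zeros(slen, dtype=bool)
    qi = si = ident = cols = 0
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
            continue
        n = int(num)
        num = ""
        cols += n
        if ch == "=":
            qmask[qi : qi + n] = True
            smask[si : si + n] = True
            ident += n
            qi += n
            si += n
        elif ch == "X":
            qi += n
            si += n
        elif ch == "I":  # consumes query only
            qi += n
        elif ch == "D":  # consumes subject only
            si += n
    return ident, cols, qmask, smask


def align_pair(
    a: Genome,
    b: Genome,
    k: int = 13,
    min_identical: int = 30,
    min_block_identity: float = 0.65,
    min_anchors: int = 2,
) -> list[AlignmentBlock]:
    """Local similarity blocks between two genomes, both strands.

    Chance k-mer anchors in unrelated sequence produce chains that are
    either single-anchor or low-identity; the ``min_anchors`` /
    ``min_block_identity`` / ``min_identical`` filters drop that background.
    A self comparison always yields the full-length identity block.
    """
    if not a.sequence or not b.sequence:
        raise ValueError("cannot align empty sequences")
    blocks: list[AlignmentBlock] = []
    index = KmerIndex(b, k=k)
    edge_pad = 200  # recover block ends that lack anchors (e.g. repeat-masked)
    for strand, query in (("+", a.sequence), ("-", reverse_complement(a.sequence))):
        anchors = index.hits(query)
        for qs, qe, ss, se, n_anc in _chain_anchors(anchors, k):
            if n_anc < min_anchors and (qe - qs) < 2 * k:
                continue
            ext = min(qs, ss, edge_pad)
            qs, ss = qs - ext, ss - ext
            ext = min(len(query) - qe, len(b) - se, edge_pad)
            qe, se = qe + ext, se + ext
            qseq = query[qs:qe]
            sseq = b.sequence[ss:se]
            res = edlib.align(qseq, sseq, task="path", mode="NW")
            ident, cols, qmask, smask = _cigar_walk(res["cigar"], qe - qs, se - ss)
            if ident < min_identical or ident / cols < min_block_identity:
                continue
            if strand == "+":
                q_int = (qs, qe)
            else:  # map back to forward coordinates of a
                q_int = (len(a) - qe, len(a) - qs)
                qmask = qmask[::-1]
            blocks.append(
                AlignmentBlock(a.id, b.id, q_int, (ss, se), strand, ident, cols,
                               qmask, smask)
            )
    # deduplicate identical intervals found via overlapping chains
    uniq = {}
    for blk in blocks:
        key = (blk.query_interval, blk.subject_interval, blk.strand)
        if key not in uniq or blk.identical_positions > uniq[key].identical_positions:
            uniq[key] = blk
    return sorted(
        uniq.values(),
        key=lambda x: (-x.identical_positions, x.query_interval, x.subject_interval),
    )


# ---------------------------------------------------------------------------
# similarity


def intergenomic_similarity(
    blocks: Sequence[AlignmentBlock], a: Genome, b: Genome
) -> tuple[float, float, float]:
    """Similarity percentage plus aligned fractions of each genome.

    Blocks carrying per-position match masks contribute the union of their
    matched positions (each genome position counts at most once, the exact
    meaning of merging overlapping aligned intervals).  Count-only blocks
    (tabular ingest) are consumed in decreasing ``identical_positions``
    order (ties by query then subject start) with overlaps truncated and
    identical positions pro-rated over the clipped span.
    """
    for blk in blocks:
        if {blk.query_id, blk.subject_id} - {a.id, b.id}:
            raise ValueError(
                f"block {blk.query_id}~{blk.subject_id} does not reference {a.id}/{b.id}"
            )
    claimed = {a.id: np.zeros(len(a), dtype=bool), b.id: np.zeros(len(b), dtype=bool)}
    matched = {a.id: np.zeros(len(a), dtype=bool), b.id: np.zeros(len(b), dtype=bool)}
    prorated = {a.id: 0.0, b.id: 0.0}
    ordered = sorted(
        blocks,
        key=lambda x: (-x.identical_positions, x.query_interval, x.subject_interval),
    )
    for blk in ordered:
        for gid, (s, e), mask in (
            (blk.query_id, blk.query_interval, blk.query_match),
            (blk.subject_id, blk.subject_interval, blk.subject_match),
        ):
            if mask is not None:
                matched[gid][s:e] |= mask
            elif e > s:
                free = ~claimed[gid][s:e]
                prorated[gid] += blk.identical_positions * free.sum() / (e - s)
            claimed[gid][s:e] = True
    id_a = matched[a.id].sum() + prorated[a.id]
    id_b = matched[b.id].sum() + prorated[b.id]
    sim = 100.0 * (id_a + id_b) / (len(a) + len(b))
    frac_a = claimed[a.id].sum() / len(a)
    frac_b = claimed[b.id].sum() / len(b)
    return min(sim, 100.0), frac_a, frac_b


def similarity_matrix(
    genomes: Sequence[Genome], blocks_by_pair: Mapping[tuple[str, str], Sequence[AlignmentBlock]] | None = None,
    **align_kwargs,
) -> SimilarityMatrix:
    """All-pairs intergenomic similarities (internal aligner by default).

    ``blocks_by_pair`` may supply precomputed alignments (e.g. ingested from
    BLAST tabular files) keyed by (query_id, subject_id).
    """
    if len(genomes) < 2:
        raise ValueError("need at least 2 genomes")
    check_unique_ids(genomes)
    n = len(genomes)
    sims = np.full((n, n), 100.0)
    frac = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = genomes[i], genomes[j]
            if blocks_by_pair is not None:
                blocks = list(blocks_by_pair.get((a.id, b.id), ())) + [
                    blk for blk in blocks_by_pair.get((b.id, a.id), ())
                ]
            else:
                blocks = align_pair(a, b, **align_kwargs)
            s, fa, fb = intergenomic_similarity(blocks, a, b)
            sims[i, j] = sims[j, i] = s
            frac[i, j] = fa
            frac[j, i] = fb
    return SimilarityMatrix([g.id for g in genomes], sims, frac)


# ---------------------------------------------------------------------------
# demarcation


def cluster_at_threshold(
    matrix: SimilarityMatrix, threshold: float, level: str | None = None,
    epsilon: float = STRAIN_EPSILON,
) -> TaxonPartition:
    """Single-linkage demarcation: connected components of the >= threshold graph.

    For a 100% threshold, equality is tested within ``epsilon`` percentage
    points to absorb floating point in the similarity computation.
    """
    if not (0.0 < threshold <= 100.0):
        raise ValueError("threshold must be in (0, 100]")
    eff = threshold - epsilon if threshold >= 100.0 else threshold
    n = len(matrix.ids)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if matrix.values[i, j] >= eff:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)
    roots = [find(i) for i in range(n)]
    # deterministic cluster names: smallest member id
    members: dict[int, list[str]] = {}
    for gid, r in zip(matrix.ids, roots):
        members.setdefault(r, []).append(gid)
    names = {r: f"c_{min(ms)}" for r, ms in members.items()}
    return TaxonPartition(
        level or f"t{threshold:g}",
        {gid: names[r] for gid, r in zip(matrix.ids, roots)},
        threshold,
    )


def demarcate_taxa(
    matrix: SimilarityMatrix,
    strain_threshold: float = STRAIN_THRESHOLD,
    species_threshold: float = SPECIES_THRESHOLD,
    genus_threshold: float = GENUS_THRESHOLD,
) -> dict[str, TaxonPartition]:
    """Strain / species / genus partitions at 100 / 95 / 70 % similarity."""
    parts = {
        "strain": cluster_at_threshold(matrix, strain_threshold, "strain"),
        "species": cluster_at_threshold(matrix, species_threshold, "species"),
        "genus": cluster_at_threshold(matrix, genus_threshold, "genus"),
    }
    assert parts["strain"].refines(parts["species"])
    assert parts["species"].refines(parts["genus"])
    return parts


# ---------------------------------------------------------------------------
# BLAST tabular interop (12-column, 1-based inclusive coordinates)

BLAST_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def read_blast_tabular(path: str | Path) -> dict[tuple[str, str], list[AlignmentBlock]]:
    """Ingest 12-column BLASTN tabular output as alignment blocks.

    Minus-strand hits are encoded by sstart > send; identical positions are
    reconstructed as pident/100 * length.
    """
    df = pd.read_csv(path, sep="\t", names=BLAST_COLUMNS, comment="#")
    out: dict[tuple[str, str], list[AlignmentBlock]] = {}
    for row in df.itertuples(index=False):
        ss, se = int(row.sstart), int(row.send)
        strand = "+" if ss <= se else "-"
        if strand == "-":
            ss, se = se, ss
        blk = AlignmentBlock(
            str(row.qseqid), str(row.sseqid),
            (int(row.qstart) - 1, int(row.qend)),
            (ss - 1, se),
            strand,
            float(row.pident) / 100.0 * int(row.length),
            int(row.length),
        )
        out.setdefault((blk.query_id, blk.subject_id), []).append(blk)
    return out


def write_similarity_tsv(matrix: SimilarityMatrix, path: str | Path) -> None:
    matrix.to_frame().to_csv(path, sep="\t", index_label="genome")


def write_partition_tsv(partitions: Mapping[str, TaxonPartition], path: str | Path) -> None:
    levels = list(partitions)
    ids = sorted(next(iter(partitions.values())).assignment)
    with open(path, "w") as fh:
        fh.write("genome_id\t" + "\t".join(levels) + "\n")
        for gid in ids:
            fh.write(gid + "\t" + "\t".join(partitions[lv].assignment[gid] for lv in levels) + "\n")
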