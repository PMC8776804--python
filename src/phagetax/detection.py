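"""Presence calling and normalized abundances from metagenome read mappings.

Per-read identity is (aligned bases - edit distance) / aligned bases, the
edit distance including indels (SAM NM semantics).  Genome coverage breadth
at an identity threshold is the fraction of genome positions overlapped at
least once by qualifying alignments (the union of intervals, so depth never
inflates breadth).  The presence rules are fixed, strict inequalities:

* bacterium       present when > 60% of the genome is covered at >= 95% identity
* phage           present when > 75% at >= 90% identity
* phage relative  present when > 60% at >= 70% identity

and the relative abundance of a genome in a sample is

    qualifying aligned bases / genome length (bp) / library size (Gb).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .community import Read, ReadSet

#: (identity threshold %, breadth fraction that must be exceeded) per entity kind
PRESENCE_RULES: dict[str, tuple[float, float]] = {
    "bacterium": (95.0, 0.60),
    "phage": (90.0, 0.75),
    "relative": (70.0, 0.60),
}


@dataclass(frozen=True)
class ReadAlignment:
    read_id: str
    genome_id: str
    start: int  # 0-based half-open genome interval
    end: int
    aligned_bases: int
    edit_distance: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.edit_distance > self.aligned_bases:
            raise ValueError("edit distance cannot exceed aligned bases")
        if self.end <= self.start:
            raise ValueError("empty alignment interval")


@dataclass
class CoverageProfile:
    genome_id: str
    identity_threshold: float  # percentage
    covered_fraction: float
    qualifying_bases: int
    n_foreign_ignored: int = 0


@dataclass
class PresenceCall:
    genome_id: str
    kind: str
    present: bool
    identity_threshold: float
    breadth_threshold: float
    covered_fraction: float


@dataclass
class AbundanceRecord:
    genome_id: str
    identity_threshold: float
    abundance: float  # bases per genome-base per Gb
    library_gb: float


def read_identity(aln: ReadAlignment) -> float:
    """(aligned bases - edit distance) / aligned bases, in [0, 1]."""
    if aln.aligned_bases <= 0:
        raise ValueError("aligned bases must be > 0")
    return (aln.aligned_bases - aln.edit_distance) / aln.aligned_bases


def coverage_profile(
    alignments: Sequence[ReadAlignment],
    genome_id: str,
    genome_length: int,
    min_identity: float,
) -> CoverageProfile:
    """Breadth of coverage by alignments with identity >= ``min_identity`` %.

    Alignments referencing other genomes are ignored (counted in
    ``n_foreign_ignored``); qualifying bases sum the aligned read bases of
    the alignments that pass the identity filter.
    """
    if genome_length <= 0:
        raise ValueError("genome length must be > 0")
    foreign = 0
    events = np.zeros(genome_length + 1, dtype=np.int64)
    qualifying = 0
    for aln in alignments:
        if aln.genome_id != genome_id:
            foreign += 1
            continue
        if read_identity(aln) * 100.0 < min_identity:
            continue
        qualifying += aln.aligned_bases
        events[max(aln.start, 0)] += 1
        events[min(aln.end, genome_length)] -= 1
    depth = np.cumsum(events[:-1])
    covered = float((depth > 0).sum()) / genome_length
    return CoverageProfile(genome_id, min_identity, covered, int(qualifying), foreign)


def call_presence(
    profiles: Mapping[float, CoverageProfile], kind: str
) -> PresenceCall:
    """Apply the fixed rule for ``kind`` (strict > on the breadth)."""
    if kind not in PRESENCE_RULES:
        raise ValueError(f"unknown entity kind {kind!r}")
    identity, breadth = PRESENCE_RULES[kind]
    if identity not in profiles:
        raise ValueError(f"no coverage profile at the {identity:g}% identity threshold")
    prof = profiles[identity]
    return PresenceCall(
        prof.genome_id, kind, prof.covered_fraction > breadth,
        identity, breadth, prof.covered_fraction,
    )


def normalized_abundance(
    qualifying_bases: int, genome_length: int, library_gb: float,
    identity_threshold: float = 90.0, genome_id: str = "",
) -> AbundanceRecord:
    """bases aligned at >= x% identity / genome size in bases / library size in Gb."""
    if genome_length <= 0 or library_gb <= 0:
        raise ValueError("genome length and library size must be > 0")
    if qualifying_bases < 0:
        raise ValueError("qualifying bases must be >= 0")
    ab = qualifying_bases / genome_length / library_gb
    return AbundanceRecord(genome_id, identity_threshold, ab, library_gb)


def phage_host_ratio(phage: AbundanceRecord, host: AbundanceRecord) -> float | None:
    """Phage abundance over host abundance; None when the host is undetected
    (the undefined ratio is reported as such, never as infinity)."""
    if host.abundance == 0:
        return None
    return phage.abundance / host.abundance


def format_ratio(ratio: float | None) -> str:
    """Table formatting: integers for ratios >= 10, two decimals below that."""
    if ratio is None:
        return "undefined"
    return str(int(round(ratio))) if ratio >= 10 else f"{ratio:.2f}"


# ---------------------------------------------------------------------------
# ingest: truth alignments, SAM, PAF


def alignments_from_truth(readset: ReadSet) -> list[ReadAlignment]:
    """Perfect-mapper alignments from simulated reads (origin interval is the
    alignment, planted substitutions are the edit distance)."""
    return [
        ReadAlignment(r.id, r.origin_id, r.start, r.end,
                      r.end - r.start, r.n_substitutions, r.strand)
        for r in readset.reads
    ]


def read_sam(
    path: str | Path, include_secondary: bool = False
) -> list[ReadAlignment]:
    """Read alignments from SAM/BAM; requires the NM tag (or an MD tag from
    which NM is reconstructed) for edit distances."""
    import pysam

    out: list[ReadAlignment] = []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped:
                continue
            if not include_secondary and (rec.is_secondary or rec.is_supplementary):
                continue
            if rec.has_tag("NM"):
                nm = int(rec.get_tag("NM"))
            elif rec.has_tag("MD"):
                md = str(rec.get_tag("MD"))
                mismatches = sum(1 for ch in md if ch in "ACGTN")
                indels = sum(
                    ln for op, ln in (rec.cigartuples or []) if op in (1, 2)
                )
                nm = mismatches + indels
            else:
                raise ValueError(
                    f"alignment {rec.query_name} lacks both NM and MD tags; "
                    "identity cannot be computed"
                )
            aligned = rec.query_alignment_length
            out.append(
                ReadAlignment(
                    rec.query_name, fh.get_reference_name(rec.reference_id),
                    rec.reference_start, rec.reference_end,
                    aligned, nm, "-" if rec.is_reverse else "+",
                )
            )
    return out


def read_paf(path: str | Path) -> list[ReadAlignment]:
    """Read alignments from PAF: residue matches (col 10) and alignment block
    length (col 11) give identity; target interval comes from cols 8-9."""
    out: list[ReadAlignment] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            matches, block = int(f[9]), int(f[10])
            out.append(
                ReadAlignment(
                    f[0], f[5], int(f[7]), int(f[8]),
                    block, block - matches, f[4],
                )
            )
    return out


# ---------------------------------------------------------------------------
# tabular summaries


def detection_table(
    alignments: Sequence[ReadAlignment],
    genome_lengths: Mapping[str, int],
    kinds: Mapping[str, str],
    library_gb: float,
) -> pd.DataFrame:
    """Presence + abundance per genome at its rule's identity threshold."""
    rows = []
    for gid, kind in kinds.items():
        identity, breadth = PRESENCE_RULES[kind]
        prof = coverage_profile(alignments, gid, genome_lengths[gid], identity)
        call = call_presence({identity: prof}, kind)
        ab = normalized_abundance(
            prof.qualifying_bases, genome_lengths[gid], library_gb, identity, gid
        )
        rows.append(
            {
                "genome": gid, "kind": kind,
                "identity_threshold": identity,
                "covered_fraction": prof.covered_fraction,
                "qualifying_bases": prof.qualifying_bases,
                "abundance": ab.abundance,
                "present": call.present,
            }
        )
    return pd.DataFrame(rows)


def ratio_table(abundances: pd.DataFrame) -> pd.DataFrame:
    """Join phage and host abundance rows into phage/host ratios.

    Expects columns: sample, name, kind (phage|relative|host), abundance,
    host_name (for phage/relative rows: the matching host row's name).
    """
    hosts = abundances[abundances["kind"] == "host"].set_index(["sample", "name"])
    rows = []
    for row in abundances[abundances["kind"] != "host"].itertuples(index=False):
        key = (row.sample, row.host_name)
        ratio = None
        if key in hosts.index and hosts.loc[key, "abundance"] > 0:
            ratio = float(row.abundance) / float(hosts.loc[key, "abundance"])
        rows.append(
            {
                "sample": row.sample, "phage": row.name, "kind": row.kind,
                "host": row.host_name,
                "phage_abundance": row.abundance,
                "host_abundance": float(hosts.loc[key, "abundance"]) if key in hosts.index else np.nan,
                "ratio": np.nan if ratio is None else ratio,
                "ratio_formatted": format_ratio(ratio),
            }
        )
    return pd.DataFrame(rows)
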