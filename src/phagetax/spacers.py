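"""CRISPR spacer matching against phage genomes and host-phage assignment.

Candidate loci are seeded by exact 10-mer word matches on both strands and
extended to full-spacer semi-global alignments.  A reported match must obey
all three constraints used for spacer mapping:

* total gapped positions at most 20% of the spacer length,
* no single gap event longer than 5 bp,
* effective mismatches (substitutions + gapped positions, i.e. gaps counted
  as mismatches) at most 50% of the spacer length.

Host-phage assignment keeps only matches with at most ``max_mismatch``
effective mismatches (1 by default; the "fewer than two mismatches" variant
used for public spacer databases collapses to the same value).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import edlib
import pandas as pd

from .genome import Genome, reverse_complement

WORD_LENGTH = 10
MAX_GAP_EVENT = 5
MAX_GAP_FRACTION = 0.20
MAX_MISMATCH_FRACTION = 0.50
DEFAULT_MAX_MISMATCH = 1


@dataclass(frozen=True)
class Spacer:
    spacer_id: str
    host_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("spacer sequence must be non-empty")
        if set(self.sequence) - set("ACGT"):
            raise ValueError(f"spacer {self.spacer_id!r} has non-ACGT characters")


@dataclass(frozen=True)
class SpacerMatch:
    spacer_id: str
    genome_id: str
    start: int  # 0-based half-open genome interval
    end: int
    strand: str
    substitutions: int
    gap_positions: int
    gap_events: tuple[int, ...]

    @property
    def effective_mismatches(self) -> int:
        return self.substitutions + self.gap_positions


def effective_mismatches(substitutions: int, gap_events: Sequence[int]) -> int:
    """Substitutions plus gapped positions; every inserted or deleted base
    counts as one mismatch."""
    return substitutions + sum(gap_events)


def _parse_cigar(cigar: str) -> tuple[int, tuple[int, ...]]:
    """(substitutions, gap event lengths) from an extended CIGAR string."""
    subs = 0
    gaps: list[int] = []
    num = ""
    prev_gap = False
    for ch in cigar:
        if ch.isdigit():
            num += ch
            continue
        n = int(num)
        num = ""
        if ch == "X":
            subs += n
            prev_gap = False
        elif ch in "ID":
            if prev_gap:
                gaps[-1] += n  # adjacent I/D runs form one gap event
            else:
                gaps.append(n)
            prev_gap = True
        else:
            prev_gap = False
    return subs, tuple(gaps)


def find_spacer_hits(
    spacer: Spacer, genome: Genome, max_mismatch: int | None = None
) -> list[SpacerMatch]:
    """All constraint-satisfying loci of a spacer in a genome, best first.

    Matches are ordered by effective mismatches, ties by genome position.
    A locus with no exact 10-mer anchor is undetectable by design (word
    seeding); ``max_mismatch`` optionally tightens the mismatch cap below
    the 50% constraint.
    """
    L = len(spacer.sequence)
    if L < WORD_LENGTH:
        raise ValueError(f"spacer shorter than the word length ({WORD_LENGTH})")
    max_gap_total = int(MAX_GAP_FRACTION * L)
    mm_cap = int(MAX_MISMATCH_FRACTION * L)
    if max_mismatch is not None:
        mm_cap = min(mm_cap, max_mismatch)
    gseq = genome.sequence
    Lg = len(gseq)
    pad = max_gap_total + MAX_GAP_EVENT
    # genome 10-mer index
    index: dict[str, list[int]] = {}
    for i in range(Lg - WORD_LENGTH + 1):
        index.setdefault(gseq[i : i + WORD_LENGTH], []).append(i)

    hits: dict[tuple[int, int, str], SpacerMatch] = {}
    windows_seen: set[tuple[int, str]] = set()
    for strand in ("+", "-"):
        q = spacer.sequence if strand == "+" else reverse_complement(spacer.sequence)
        for qi in range(L - WORD_LENGTH + 1):
            for gpos in index.get(q[qi : qi + WORD_LENGTH], ()):
                wstart = max(gpos - qi - pad, 0)
                wend = min(gpos - qi + L + pad, Lg)
                wkey = (wstart // max(pad, 1), strand)
                if (wstart, strand) in windows_seen:
                    continue
                windows_seen.add((wstart, strand))
                res = edlib.align(q, gseq[wstart:wend], task="path", mode="HW")
                if res["editDistance"] < 0:
                    continue
                for loc_start, loc_end in res["locations"]:
                    subs, gaps = _parse_cigar(res["cigar"])
                    gap_total = sum(gaps)
                    eff = subs + gap_total
                    if gap_total > max_gap_total:
                        continue
                    if any(g > MAX_GAP_EVENT for g in gaps):
                        continue
                    if eff > mm_cap:
                        continue
                    s = wstart + loc_start
                    e = wstart + loc_end + 1
                    key = (s, e, strand)
                    if key not in hits or eff < hits[key].effective_mismatches:
                        hits[key] = SpacerMatch(
                            spacer.spacer_id, genome.id, s, e, strand,
                            subs, gap_total, gaps,
                        )
                    break  # one location per window alignment is enough
    # collapse overlapping hits on the same strand, keep the best
    chosen: list[SpacerMatch] = []
    for m in sorted(hits.values(), key=lambda m: (m.effective_mismatches, m.start, m.end)):
        if any(
            c.strand == m.strand and c.start < m.end and m.start < c.end
            for c in chosen
        ):
            continue
        chosen.append(m)
    return sorted(chosen, key=lambda m: (m.effective_mismatches, m.start, m.end))


def assign_phage_to_host(
    spacers: Sequence[Spacer],
    phages: Sequence[Genome],
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
) -> pd.DataFrame:
    """(host, phage) assignments supported by spacer matches with at most
    ``max_mismatch`` effective mismatches, best supported first."""
    if not spacers or not phages:
        raise ValueError("spacers and phages must be non-empty")
    rows: dict[tuple[str, str], dict] = {}
    for phage in phages:
        for sp in spacers:
            if len(sp.sequence) < WORD_LENGTH:
                continue
            matches = find_spacer_hits(sp, phage)
            good = [m for m in matches if m.effective_mismatches <= max_mismatch]
            if not good:
                continue
            best = good[0].effective_mismatches
            key = (sp.host_id, phage.id)
            rec = rows.setdefault(
                key,
                {"host": sp.host_id, "phage": phage.id,
                 "best_mismatch": best, "n_spacers": 0, "spacer_ids": []},
            )
            rec["n_spacers"] += 1
            rec["spacer_ids"].append(sp.spacer_id)
            rec["best_mismatch"] = min(rec["best_mismatch"], best)
    out = pd.DataFrame(
        sorted(rows.values(), key=lambda r: (r["best_mismatch"], r["host"], r["phage"]))
    )
    if out.empty:
        out = pd.DataFrame(
            columns=["host", "phage", "best_mismatch", "n_spacers", "spacer_ids"]
        )
    out["spacer_ids"] = out["spacer_ids"].apply(lambda x: ",".join(x))
    return out


# ---------------------------------------------------------------------------
# I/O (spacer FASTA header convention: hostID|spacerID)


def read_spacer_fasta(path: str | Path) -> list[Spacer]:
    from Bio import SeqIO

    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if "|" not in rec.id:
            raise ValueError(f"spacer header {rec.id!r} lacks 'hostID|spacerID'")
        host = rec.id.split("|", 1)[0]
        out.append(Spacer(rec.id, host, str(rec.seq).upper()))
    return out


def matches_to_frame(matches: Iterable[SpacerMatch]) -> pd.DataFrame:
    """Match table with 1-based inclusive coordinates for interop."""
    rows = [
        {
            "spacer": m.spacer_id, "genome": m.genome_id,
            "start_1based": m.start + 1, "end_1based": m.end,
            "strand": m.strand, "substitutions": m.substitutions,
            "gap_positions": m.gap_positions,
            "effective_mismatches": m.effective_mismatches,
        }
        for m in matches
    ]
    return pd.DataFrame(
        rows, columns=["spacer", "genome", "start_1based", "end_1based", "strand",
                       "substitutions", "gap_positions", "effective_mismatches"],
    )
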