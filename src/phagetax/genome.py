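"""Core sequence containers shared by every stage of the pipeline.

A :class:`Genome` is a named nucleotide sequence, optionally carrying the
planted taxonomic truth labels produced by the synthetic community
generator (``strain``/``species``/``genus``/``family``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class Genome:
    """A named nucleotide sequence over {A, C, G, T} (N tolerated on input)."""

    id: str
    sequence: str
    truth_labels: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("genome id must be non-empty")
        if not self.sequence:
            raise ValueError(f"genome {self.id!r} has an empty sequence")
        self.sequence = self.sequence.upper()

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def gc(self) -> float:
        s = self.sequence
        return (s.count("G") + s.count("C")) / len(s)


def check_unique_ids(genomes: Sequence[Genome]) -> None:
    seen: set[str] = set()
    for g in genomes:
        if g.id in seen:
            raise ValueError(f"duplicate genome id {g.id!r}")
        seen.add(g.id)


def read_fasta(path: str | Path) -> list[Genome]:
    genomes = [Genome(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
    if not genomes:
        raise ValueError(f"no FASTA records found in {path}")
    check_unique_ids(genomes)
    return genomes


def write_fasta(genomes: Iterable[Genome], path: str | Path, width: int = 70) -> None:
    records = [SeqRecord(Seq(g.sequence), id=g.id, description="") for g in genomes]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def write_truth_table(genomes: Iterable[Genome], path: str | Path) -> None:
    """Write planted truth labels as TSV (genome_id, strain, species, genus, family)."""
    with open(path, "w") as fh:
        fh.write("genome_id\tstrain\tspecies\tgenus\tfamily\n")
        for g in genomes:
            lab: Mapping[str, str] = g.truth_labels or {}
            fh.write(
                "\t".join(
                    [g.id]
                    + [lab.get(k, "NA") for k in ("strain", "species", "genus", "family")]
                )
                + "\n"
            )
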