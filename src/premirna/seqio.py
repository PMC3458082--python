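"""Sequence and interval I/O with a single internal coordinate contract.

All coordinates inside the package are 0-based half-open on the forward
strand (BED/SAM convention).  1-based inclusive dialects are converted at
the file boundary and never appear internally.  Sequences are held as
uppercase RNA; DNA input is converted (T -> U) on read and written back
as-is (RNA alphabet) on output.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

RNA_ALPHABET = frozenset("ACGUN")

_COMPLEMENT = str.maketrans("ACGUN", "UGCAN")


class FastaFormatError(ValueError):
    """Malformed FASTA input (empty body, bad alphabet...)."""


class IntervalFormatError(ValueError):
    """Malformed interval line (start >= end, bad strand...)."""


class BoundsError(ValueError):
    """Interval falls outside its contig; nothing is silently padded."""


@dataclasses.dataclass(frozen=True)
class GenomicInterval:
    """Half-open interval [start, end) on one strand of a contig."""

    seq_id: str
    start: int
    end: int
    strand: str = "+"
    name: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise IntervalFormatError(
                f"invalid interval {self.seq_id}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise IntervalFormatError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclasses.dataclass(frozen=True)
class SequenceRecord:
    """Named uppercase RNA sequence over {A, C, G, U, N}."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise FastaFormatError("record with empty id")
        if not self.sequence:
            raise FastaFormatError(f"record {self.id!r} has empty sequence")
        bad = set(self.sequence) - RNA_ALPHABET
        if bad:
            raise FastaFormatError(
                f"record {self.id!r} contains non-RNA characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


def normalize(seq: str) -> str:
    """Uppercase and convert DNA T to RNA U."""
    return seq.upper().replace("T", "U")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into normalized records, preserving file order."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = normalize(str(rec.seq))
        if not seq:
            raise FastaFormatError(f"record {rec.id!r} has empty sequence")
        records.append(SequenceRecord(id=rec.id, sequence=seq))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    bio = [SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records]
    SeqIO.write(bio, str(path), "fasta")


def read_intervals(path: str | Path, dialect: str = "bed") -> list[GenomicInterval]:
    """Read intervals from BED6 (0-based half-open) or a whitespace TSV
    dialect (``seq_id start end strand`` with 1-based inclusive coordinates,
    converted on read)."""
    if dialect not in ("bed", "tsv"):
        raise ValueError(f"unknown dialect {dialect!r}")
    out: list[GenomicInterval] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split()
        try:
            if dialect == "bed":
                seq_id, start, end = fields[0], int(fields[1]), int(fields[2])
                name = fields[3] if len(fields) > 3 else ""
                strand = fields[5] if len(fields) > 5 else "+"
            else:
                seq_id, start, end = fields[0], int(fields[1]) - 1, int(fields[2])
                strand = fields[3] if len(fields) > 3 else "+"
                name = ""
            out.append(GenomicInterval(seq_id, start, end, strand, name))
        except (IndexError, ValueError, IntervalFormatError) as exc:
            raise IntervalFormatError(f"{path} line {lineno}: {exc}") from exc
    return out


def write_bed(intervals: Iterable[tuple[GenomicInterval, float]], path: str | Path) -> None:
    """Write (interval, score) pairs as BED6; score scaled to 0-1000."""
    with open(path, "w") as fh:
        for iv, score in intervals:
            fh.write(
                f"{iv.seq_id}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t"
                f"{int(round(1000 * score))}\t{iv.strand}\n"
            )


def extract_interval(
    genome: dict[str, SequenceRecord] | list[SequenceRecord],
    iv: GenomicInterval,
) -> SequenceRecord:
    """Extract the interval sequence; minus-strand intervals are
    reverse-complemented.  Out-of-bounds access raises rather than pads."""
    if isinstance(genome, list):
        genome = {r.id: r for r in genome}
    if iv.seq_id not in genome:
        raise BoundsError(f"contig {iv.seq_id!r} not in genome")
    contig = genome[iv.seq_id]
    if iv.end > len(contig):
        raise BoundsError(
            f"interval {iv.seq_id}:{iv.start}-{iv.end} exceeds contig "
            f"length {len(contig)}"
        )
    seq = contig.sequence[iv.start : iv.end]
    if iv.strand == "-":
        seq = reverse_complement(seq)
    name = iv.name or f"{iv.seq_id}:{iv.start}-{iv.end}({iv.strand})"
    return SequenceRecord(id=name, sequence=seq)
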