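"""Seeded synthetic fixtures: designed hairpin precursors in a toy genome,
pseudohairpin negatives, and small-RNA read pileups.

The generators emulate the data shapes the rest of the package consumes:

* :func:`gen_hairpin_set` — stem-loop precursors with complementary arms
  (controlled mismatch rate), a recorded ~21-nt "mature" interval on one
  arm, each embedded at a known locus of a random background genome.
* :func:`gen_pseudohairpins` — GC-skewed random sequences kept only when
  they fold into at least one hairpin, tagged with negative-source
  categories (r/sno/sn/t/ps).
* :func:`gen_reads` — per planted locus, two read stacks over the two
  arms (summits within 75 bp) plus uniform background reads; a truth
  table accompanies the reads.

Everything is a pure function of (parameters, seed).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np

from .folding import NoHairpinError, find_terminal_loop, fold
from .seqio import GenomicInterval, SequenceRecord, reverse_complement

_BASES = np.array(list("ACGU"))

NEGATIVE_CATEGORIES = ("r", "sno", "sn", "t", "ps")


@dataclasses.dataclass
class HairpinSet:
    """Designed precursors plus their toy-genome embedding."""

    precursors: list[SequenceRecord]
    matures: dict[str, tuple[int, int]]  # precursor-local, half-open
    genome: list[SequenceRecord]
    loci: list[GenomicInterval]  # precursor position in the genome


def _random_seq(rng: np.random.Generator, n: int, gc: float = 0.5) -> str:
    p_gc = gc / 2.0
    p_au = (1.0 - gc) / 2.0
    return "".join(rng.choice(_BASES, size=n, p=[p_au, p_gc, p_gc, p_au]))


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            out[i] = rng.choice([b for b in "ACGU" if b != out[i]])
    return "".join(out)


def gen_hairpin_set(
    n: int = 30,
    stem_len: tuple[int, int] = (25, 35),
    loop_len: tuple[int, int] = (6, 15),
    mature_len: int = 21,
    mutation_rate: float = 0.05,
    mature_arm: str = "5p",
    spacer: int = 600,
    gc: float = 0.55,
    seed: int = 0,
) -> HairpinSet:
    """Design ``n`` stem-loop precursors and embed them in one toy contig.

    Each precursor is ``5'-arm + loop + revcomp(5'-arm with mutations)``;
    the mature interval sits on the requested arm.  Loci are separated by
    random spacers long enough that every loop center has the 100-nt
    flanks a 200-nt candidate window needs.
    """
    if stem_len[0] < mature_len:
        raise ValueError("stem must be at least mature_len")
    if not (0 <= mutation_rate < 0.5):
        raise ValueError("mutation_rate must be in [0, 0.5)")
    if mature_arm not in ("5p", "3p"):
        raise ValueError("mature_arm must be '5p' or '3p'")
    rng = np.random.default_rng(seed)
    precursors: list[SequenceRecord] = []
    matures: dict[str, tuple[int, int]] = {}
    chunks: list[str] = []
    loci: list[GenomicInterval] = []
    pos = 0
    for i in range(n):
        s_len = int(rng.integers(stem_len[0], stem_len[1] + 1))
        l_len = int(rng.integers(loop_len[0], loop_len[1] + 1))
        arm5 = _random_seq(rng, s_len, gc=gc)
        loop = _random_seq(rng, l_len, gc=0.3)
        arm3 = _mutate(rng, reverse_complement(arm5), mutation_rate)
        seq = arm5 + loop + arm3
        pid = f"synthpre-{i:03d}"
        if mature_arm == "5p":
            off = int(rng.integers(0, s_len - mature_len + 1))
            mature = (off, off + mature_len)
        else:
            off = int(rng.integers(0, s_len - mature_len + 1))
            mature = (s_len + l_len + off, s_len + l_len + off + mature_len)
        precursors.append(SequenceRecord(id=pid, sequence=seq))
        matures[pid] = mature
        gap = _random_seq(rng, spacer + int(rng.integers(0, 50)))
        chunks.append(gap)
        pos += len(gap)
        chunks.append(seq)
        loci.append(GenomicInterval("chrS", pos, pos + len(seq), "+", pid))
        pos += len(seq)
    chunks.append(_random_seq(rng, spacer))
    genome = [SequenceRecord(id="chrS", sequence="".join(chunks))] if n else []
    return HairpinSet(precursors, matures, genome, loci)


def gen_pseudohairpins(
    n: int = 30,
    length: tuple[int, int] = (320, 420),
    gc: float = 0.6,
    categories: Sequence[str] = NEGATIVE_CATEGORIES,
    engine: str = "auto",
    seed: int = 0,
) -> list[tuple[SequenceRecord, str]]:
    """Random GC-skewed sequences kept when they fold into >= 1 hairpin
    loop, cyclically tagged with negative-source categories."""
    rng = np.random.default_rng(seed)
    out: list[tuple[SequenceRecord, str]] = []
    i = 0
    while len(out) < n:
        L = int(rng.integers(length[0], length[1] + 1))
        seq = _random_seq(rng, L, gc=gc)
        try:
            (_, _), center = find_terminal_loop(fold(seq, engine=engine))
        except NoHairpinError:
            continue
        # keep only sequences whose loop center leaves room for the
        # 200-nt loop-centered window downstream
        if center < 99 or center + 101 > L:
            continue
        cat = categories[len(out) % len(categories)]
        out.append((SequenceRecord(id=f"pseudo-{i:03d}", sequence=seq), cat))
        i += 1
    return out


@dataclasses.dataclass
class ReadSet:
    """Simulated small-RNA reads with their true genomic placements."""

    reads: list[tuple[str, str]]  # (read_id, sequence)
    alignments: list[tuple[str, GenomicInterval]]
    truth: list[dict]  # per-region summit bookkeeping


def gen_reads(
    genome: Sequence[SequenceRecord],
    regions: Sequence[GenomicInterval],
    arm_offsets: Sequence[tuple[int, int]] | None = None,
    depth: int = 25,
    read_len: tuple[int, int] = (16, 36),
    background_fraction: float = 0.1,
    jitter: int = 2,
    seed: int = 0,
) -> ReadSet:
    """Simulate two read stacks per planted region plus background noise.

    ``arm_offsets`` gives, per region, the region-local start of the two
    arm stacks (summits <= 75 bp apart); by default the stacks sit at the
    region's 5' end and at 55 bp downstream.  ``background_fraction`` of
    all reads land uniformly on the genome.
    """
    if not (16 <= read_len[0] <= read_len[1]):
        raise ValueError("read lengths must be >= 16 and ordered")
    rng = np.random.default_rng(seed)
    contigs = {r.id: r for r in genome}
    reads: list[tuple[str, str]] = []
    aligns: list[tuple[str, GenomicInterval]] = []
    truth: list[dict] = []
    rid = 0

    def emit(seq_id: str, start: int) -> None:
        nonlocal rid
        L = int(rng.integers(read_len[0], read_len[1] + 1))
        contig = contigs[seq_id]
        start = max(0, min(start, len(contig) - L))
        name = f"read-{rid:06d}"
        rid += 1
        reads.append((name, contig.sequence[start : start + L]))
        aligns.append((name, GenomicInterval(seq_id, start, start + L, "+", name)))

    for k, region in enumerate(regions):
        off1, off2 = (
            arm_offsets[k] if arm_offsets is not None else (0, min(55, len(region) - 1))
        )
        if abs(off2 - off1) > 75:
            raise ValueError("arm stacks must be <= 75 bp apart")
        for off in (off1, off2):
            for _ in range(depth):
                emit(region.seq_id, region.start + off + int(rng.integers(-jitter, jitter + 1)))
        truth.append(
            {
                "region": region,
                "summits": (region.start + off1, region.start + off2),
                "reads_per_arm": depth,
            }
        )
    n_signal = 2 * depth * len(regions)
    n_background = int(round(n_signal * background_fraction / max(1e-12, 1 - background_fraction)))
    for _ in range(n_background):
        contig = contigs[rng.choice(sorted(contigs))]
        emit(contig.id, int(rng.integers(0, max(1, len(contig) - read_len[1]))))
    return ReadSet(reads=reads, alignments=aligns, truth=truth)


def write_fastq(reads: Sequence[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in reads:
            fh.write(f"@{name}\n{seq.replace('U', 'T')}\n+\n{'I' * len(seq)}\n")


def write_alignments_bed(
    alignments: Sequence[tuple[str, GenomicInterval]], path: str | Path
) -> None:
    with open(path, "w") as fh:
        for name, iv in alignments:
            fh.write(f"{iv.seq_id}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")
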