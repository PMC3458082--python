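"""Small-RNA read-guided candidate discovery.

Pipeline: collapse reads to unique sequences with counts, subtract reads
already explained by annotation (mRNA, then other ncRNA, then known
precursors), cluster the surviving mapped reads, and keep clusters whose
coverage shows the two-arm signature — at least two coverage peaks with
summits no more than 75 bp apart.  Each passing cluster yields a 250-nt
region centered on the cluster midpoint, which is re-centered on its
terminal loop, classified, and reported with a reads-per-million
abundance.

Read mapping itself is external; alignments are consumed as BED or SAM.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .folding import (
    HairpinCandidate,
    NoHairpinError,
    find_terminal_loop,
    fold,
    make_candidate,
)
from .model import BaggedModel, bag_predict
from .pipeline import candidate_vector
from .profiles import ProfileLibrary
from .seqio import BoundsError, FastaFormatError, GenomicInterval, SequenceRecord, normalize

logger = logging.getLogger(__name__)

REGION_LEN = 250
MAX_SUMMIT_SEP = 75

FILTER_ORDER = ("mRNA", "ncRNA", "pre-miRNA")


class CascadeError(ValueError):
    pass


@dataclasses.dataclass(frozen=True)
class UniqueRead:
    id: str
    sequence: str
    count: int


@dataclasses.dataclass
class CandidateRegion:
    interval: GenomicInterval  # length 250
    coverage: np.ndarray  # per-base over the interval
    summits: list[int]  # genomic positions of coverage peaks
    read_count: int
    rpm: float = 0.0


def read_alignments(path: str | Path) -> list[tuple[str, GenomicInterval]]:
    """Read mapped-read placements from BED6 or SAM (by extension).

    Unmapped SAM records are skipped.  Returns (read id, interval) pairs in
    file order."""
    path = Path(path)
    if path.suffix.lower() in (".sam", ".bam"):
        import pysam

        out = []
        with pysam.AlignmentFile(str(path), "r") as fh:
            for rec in fh:
                if rec.is_unmapped:
                    continue
                iv = GenomicInterval(
                    rec.reference_name,
                    rec.reference_start,
                    rec.reference_end,
                    "-" if rec.is_reverse else "+",
                    rec.query_name,
                )
                out.append((rec.query_name, iv))
        return out
    from .seqio import read_intervals

    return [(iv.name, iv) for iv in read_intervals(path, "bed")]


def read_fastq_sequences(path: str | Path) -> list[str]:
    """Plain FASTQ reader returning normalized read sequences in order."""
    seqs = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    for i in range(0, len(lines) - 3, 4):
        if not lines[i].startswith("@"):
            raise ValueError(f"{path}: malformed FASTQ at line {i + 1}")
        seqs.append(normalize(lines[i + 1]))
    return seqs


def collapse_reads(reads: Iterable[str] | str | Path) -> list[UniqueRead]:
    """Exact-sequence deduplication with counts.  The sum of counts equals
    the input read count.  Ids are assigned deterministically in order of
    decreasing count, then sequence."""
    if isinstance(reads, (str, Path)):
        reads = read_fastq_sequences(reads)
    counts: dict[str, int] = {}
    for seq in reads:
        seq = normalize(seq)
        counts[seq] = counts.get(seq, 0) + 1
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return [
        UniqueRead(id=f"u{i:06d}", sequence=seq, count=c)
        for i, (seq, c) in enumerate(ordered)
    ]


def filter_cascade(
    reads: Sequence[UniqueRead],
    category_hits: dict[str, set[str]],
    order: Sequence[str] = FILTER_ORDER,
) -> tuple[list[UniqueRead], list[dict]]:
    """Subtract annotated reads category by category in fixed order.

    ``category_hits`` maps category name to the set of read ids aligning
    to that annotation class (hit sets come from external alignments).
    Returns the surviving reads and a per-stage report with counts; the
    survivor count is monotone non-increasing and reads are conserved at
    every stage."""
    known = {r.id for r in reads}
    for cat, ids in category_hits.items():
        unknown = ids - known
        if unknown:
            raise CascadeError(
                f"hit set {cat!r} names unknown read ids: {sorted(unknown)[:5]}"
            )
    survivors = list(reads)
    report = []
    for cat in order:
        hits = category_hits.get(cat, set())
        before = len(survivors)
        removed = [r for r in survivors if r.id in hits]
        survivors = [r for r in survivors if r.id not in hits]
        report.append(
            {
                "stage": cat,
                "input": before,
                "removed": len(removed),
                "survivors": len(survivors),
                "input_read_count": sum(r.count for r in removed)
                + sum(r.count for r in survivors),
            }
        )
    return survivors, report


def _find_summits(coverage: np.ndarray, min_reads: int) -> list[int]:
    """Local maxima of a coverage track; plateaus are merged and reported
    at their central position.  Only summits with height >= min_reads
    count."""
    n = len(coverage)
    summits = []
    i = 0
    while i < n:
        j = i
        while j + 1 < n and coverage[j + 1] == coverage[i]:
            j += 1
        left = coverage[i - 1] if i > 0 else -np.inf
        right = coverage[j + 1] if j + 1 < n else -np.inf
        if coverage[i] >= min_reads and coverage[i] > left and coverage[i] > right:
            summits.append((i + j) // 2)
        i = j + 1
    return summits


def call_regions(
    alignments: Sequence[tuple[str, GenomicInterval]],
    genome: list[SequenceRecord] | dict[str, SequenceRecord],
    min_reads: int = 1,
    max_summit_sep: int = MAX_SUMMIT_SEP,
    cluster_gap: int = 250,
) -> list[CandidateRegion]:
    """Cluster mapped reads and keep clusters with the two-peak signature.

    Reads separated by more than ``cluster_gap`` start a new cluster.
    Within a cluster, coverage peaks supported by >= ``min_reads`` reads
    are paired when their summits lie <= ``max_summit_sep`` bp apart (the
    two precursor arms).  One 250-nt region is extracted per disjoint
    qualifying pair — pairs chosen greedily by combined peak height, each
    summit used once — centered on the mapped-read region, i.e. the pair's
    summit midpoint, and shifted (logged) when the contig boundary would
    be overrun."""
    if isinstance(genome, list):
        genome = {r.id: r for r in genome}
    by_contig: dict[str, list[GenomicInterval]] = {}
    for _, iv in alignments:
        by_contig.setdefault(iv.seq_id, []).append(iv)
    regions: list[CandidateRegion] = []
    for seq_id in sorted(by_contig):
        if seq_id not in genome:
            raise BoundsError(f"alignments reference unknown contig {seq_id!r}")
        contig_len = len(genome[seq_id])
        ivs = sorted(by_contig[seq_id], key=lambda v: (v.start, v.end))
        clusters: list[list[GenomicInterval]] = []
        for iv in ivs:
            if clusters and iv.start - max(v.end for v in clusters[-1]) <= cluster_gap:
                clusters[-1].append(iv)
            else:
                clusters.append([iv])
        for members in clusters:
            lo = min(v.start for v in members)
            hi = max(v.end for v in members)
            cov = np.zeros(hi - lo)
            for v in members:
                cov[v.start - lo : v.end - lo] += 1
            summits = [lo + s for s in _find_summits(cov, min_reads)]
            pairs = [
                (a, b)
                for i, a in enumerate(summits)
                for b in summits[i + 1 :]
                if abs(b - a) <= max_summit_sep
            ]
            # disjoint pairs, best-supported first
            pairs.sort(key=lambda p: (-(cov[p[0] - lo] + cov[p[1] - lo]), p[0]))
            used: set[int] = set()
            for a, b in pairs:
                if a in used or b in used:
                    continue
                used.update((a, b))
                mid = (a + b) // 2
                start = mid - REGION_LEN // 2
                if start < 0 or start + REGION_LEN > contig_len:
                    clipped = min(max(start, 0), contig_len - REGION_LEN)
                    logger.info(
                        "region at %s:%d shifted to fit contig (%d -> %d)",
                        seq_id, mid, start, clipped,
                    )
                    start = clipped
                if start < 0 or start + REGION_LEN > contig_len:
                    logger.warning(
                        "contig %s shorter than %d; pair dropped", seq_id, REGION_LEN
                    )
                    continue
                iv = GenomicInterval(seq_id, start, start + REGION_LEN, "+")
                region_cov = np.zeros(REGION_LEN)
                o_lo, o_hi = max(lo, start), min(hi, start + REGION_LEN)
                if o_lo < o_hi:
                    region_cov[o_lo - start : o_hi - start] = cov[o_lo - lo : o_hi - lo]
                n_reads = sum(
                    1 for v in members if v.start < iv.end and iv.start < v.end
                )
                regions.append(
                    CandidateRegion(
                        interval=iv,
                        coverage=region_cov,
                        summits=[a, b],
                        read_count=n_reads,
                    )
                )
    regions.sort(key=lambda r: (r.interval.seq_id, r.interval.start))
    return regions


def abundance(region: CandidateRegion, total_mapped_reads: int) -> float:
    """Reads-per-million normalization of a region's read count."""
    if total_mapped_reads <= 0:
        raise ValueError("total mapped reads must be positive")
    return 1e6 * region.read_count / total_mapped_reads


@dataclasses.dataclass
class ScoredRegion:
    region: CandidateRegion
    candidate: HairpinCandidate
    label: int
    vote_fraction: float


def classify_regions(
    regions: Sequence[CandidateRegion],
    model: BaggedModel,
    library: ProfileLibrary,
    genome: list[SequenceRecord] | dict[str, SequenceRecord],
    total_mapped_reads: int | None = None,
    engine: str = "auto",
) -> list[ScoredRegion]:
    """Re-center each 250-nt region on its terminal loop, classify the
    resulting 200-nt candidate, and attach the RPM abundance.  Regions
    with no hairpin are dropped with a log line."""
    if isinstance(genome, list):
        genome = {r.id: r for r in genome}
    total = total_mapped_reads or sum(r.read_count for r in regions)
    out: list[ScoredRegion] = []
    for region in regions:
        seq = genome[region.interval.seq_id].sequence[
            region.interval.start : region.interval.end
        ]
        try:
            (_, _), center = find_terminal_loop(fold(seq, engine=engine))
        except NoHairpinError:
            logger.info("region %s dropped: no hairpin", region.interval)
            continue
        g_center = region.interval.start + center
        try:
            cand = make_candidate(genome, region.interval.seq_id, g_center, engine=engine)
        except (BoundsError, FastaFormatError) as exc:
            logger.info("region %s dropped: %s", region.interval, exc)
            continue
        label, vote = bag_predict(model, candidate_vector(cand, library))
        region.rpm = abundance(region, total)
        out.append(ScoredRegion(region, cand, label, vote))
    return out
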