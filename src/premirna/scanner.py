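"""Genome-wide candidate scanning.

Windows are taken every ``stride`` nt on both strands; each window is
folded, re-centered on its terminal loop, featurized (profile score
included) and classified.  Windows without a hairpin are skipped.
Overlapping positive calls on the same strand are merged, keeping the
call with the highest vote fraction.  Scanning maps independently over
windows, so results are identical for any level of parallel chunking.
"""

from __future__ import annotations

import dataclasses

from .folding import NoHairpinError, find_terminal_loop, fold, make_candidate
from .model import BaggedModel, bag_predict
from .pipeline import candidate_vector
from .profiles import ProfileLibrary
from .seqio import (
    BoundsError,
    FastaFormatError,
    GenomicInterval,
    SequenceRecord,
    reverse_complement,
)

CANDIDATE_LEN = 200


@dataclasses.dataclass(frozen=True)
class ScanHit:
    interval: GenomicInterval
    label: int
    vote_fraction: float


def _scan_strand(
    contig: SequenceRecord,
    model: BaggedModel,
    library: ProfileLibrary,
    stride: int,
    strand: str,
    engine: str,
    vote_threshold: float,
) -> list[ScanHit]:
    seq = contig.sequence if strand == "+" else reverse_complement(contig.sequence)
    work = SequenceRecord(id=contig.id, sequence=seq)
    genome = {work.id: work}
    n = len(seq)
    hits: list[ScanHit] = []
    seen_centers: set[int] = set()
    for start in range(0, n - CANDIDATE_LEN + 1, stride):
        window = seq[start : start + CANDIDATE_LEN]
        if "N" in window:
            continue
        try:
            (_, _), center = find_terminal_loop(fold(window, engine=engine))
        except NoHairpinError:
            continue
        g_center = start + center
        if g_center in seen_centers:
            continue
        seen_centers.add(g_center)
        try:
            cand = make_candidate(genome, work.id, g_center, engine=engine)
        except (BoundsError, FastaFormatError):
            continue
        label, vote = bag_predict(model, candidate_vector(cand, library))
        if label == 1 and vote >= vote_threshold:
            s, e = cand.origin.start, cand.origin.end
            if strand == "-":  # map back to forward-strand coordinates
                s, e = len(contig) - e, len(contig) - s
            iv = GenomicInterval(contig.id, s, e, strand, f"{contig.id}:{g_center}")
            hits.append(ScanHit(iv, label, vote))
    return hits


def merge_hits(hits: list[ScanHit]) -> list[ScanHit]:
    """Merge overlapping same-strand calls, keeping the best-vote call's
    own 200-nt interval as the representative."""
    out: list[ScanHit] = []
    for strand in ("+", "-"):
        group = sorted(
            (h for h in hits if h.interval.strand == strand),
            key=lambda h: (h.interval.seq_id, h.interval.start),
        )
        cluster: list[ScanHit] = []
        for h in group:
            if (
                cluster
                and h.interval.seq_id == cluster[-1].interval.seq_id
                and h.interval.start < max(c.interval.end for c in cluster)
            ):
                cluster.append(h)
            else:
                if cluster:
                    out.append(max(cluster, key=lambda c: c.vote_fraction))
                cluster = [h]
        if cluster:
            out.append(max(cluster, key=lambda c: c.vote_fraction))
    return sorted(out, key=lambda h: (h.interval.seq_id, h.interval.start))


def scan_sequence(
    contig: SequenceRecord,
    model: BaggedModel,
    library: ProfileLibrary,
    stride: int = 50,
    both_strands: bool = True,
    engine: str = "auto",
    vote_threshold: float = 0.5,
) -> list[ScanHit]:
    """Scan one contig for precursor candidates; returns merged positive
    calls with their vote fractions.  Contigs shorter than 200 nt yield an
    empty result."""
    if len(contig) < CANDIDATE_LEN:
        return []
    hits = _scan_strand(contig, model, library, stride, "+", engine, vote_threshold)
    if both_strands:
        hits += _scan_strand(contig, model, library, stride, "-", engine, vote_threshold)
    return merge_hits(hits)
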