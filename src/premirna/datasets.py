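"""Training/testing set construction: loop-centered positives from
precursor + mature annotations, pseudohairpin negatives from labeled RNA
groups, and a seeded balanced split with redundancy control.
"""

from __future__ import annotations

import dataclasses
import difflib
import logging

import numpy as np

from .folding import (
    HairpinCandidate,
    NoHairpinError,
    find_terminal_loop,
    fold,
    make_candidate,
)
from .seqio import BoundsError, FastaFormatError, SequenceRecord

logger = logging.getLogger(__name__)


class QuotaError(ValueError):
    pass


@dataclasses.dataclass
class LabeledCandidate:
    candidate: HairpinCandidate
    label: int  # 1 positive, 0 negative
    source_id: str
    category: str | None = None


def _locate(haystack: str, needle: str) -> int | None:
    """Unique-occurrence substring search; None when absent or ambiguous."""
    first = haystack.find(needle)
    if first < 0 or haystack.find(needle, first + 1) >= 0:
        return None
    return first


def build_positive(
    precursors: list[SequenceRecord],
    matures: dict[str, str | tuple[int, int]],
    genome: list[SequenceRecord] | dict[str, SequenceRecord],
    engine: str = "auto",
) -> list[LabeledCandidate]:
    """One loop-centered 200-nt candidate per precursor.

    ``matures`` maps precursor id to either the mature sequence (mapped by
    unique substring search) or its precursor-local half-open interval.
    The mature interval is carried through in candidate-window coordinates
    for profile building.  Unmappable records are skipped with a logged
    reason, never silently dropped.
    """
    if isinstance(genome, list):
        genome = {r.id: r for r in genome}
    out: list[LabeledCandidate] = []
    for pre in precursors:
        mat = matures.get(pre.id)
        if mat is None:
            logger.warning("positive %s skipped: no mature annotation", pre.id)
            continue
        if isinstance(mat, str):
            start = _locate(pre.sequence, mat)
            if start is None:
                logger.warning("positive %s skipped: mature not mapped uniquely", pre.id)
                continue
            mat = (start, start + len(mat))
        m_start, m_end = mat
        if not (0 <= m_start < m_end <= len(pre)):
            logger.warning("positive %s skipped: mature interval out of bounds", pre.id)
            continue
        contig_hit = None
        for contig in genome.values():
            pos = _locate(contig.sequence, pre.sequence)
            if pos is not None:
                contig_hit = (contig.id, pos)
                break
        if contig_hit is None:
            logger.warning("positive %s skipped: precursor not located in genome", pre.id)
            continue
        try:
            (_, _), center = find_terminal_loop(fold(pre, engine=engine))
        except NoHairpinError:
            logger.warning("positive %s skipped: no hairpin loop", pre.id)
            continue
        seq_id, g_start = contig_hit
        try:
            cand = make_candidate(genome, seq_id, g_start + center, engine=engine)
        except (BoundsError, FastaFormatError) as exc:
            logger.warning("positive %s skipped: %s", pre.id, exc)
            continue
        win_mature = (
            g_start + m_start - cand.origin.start,
            g_start + m_end - cand.origin.start,
        )
        cand = dataclasses.replace(cand, mature=win_mature)
        out.append(LabeledCandidate(cand, label=1, source_id=pre.id))
    return out


def build_negative(
    rna_groups: dict[str, list[SequenceRecord]],
    engine: str = "auto",
) -> list[LabeledCandidate]:
    """Loop-centered pseudohairpin candidates from category-labeled RNA
    sequences.  Each sequence acts as its own contig: it is folded, the
    terminal-loop center found, and a 200-nt window cut around it.
    Sequences with no hairpin or insufficient flank are skipped and
    logged, tagged with their source category otherwise."""
    out: list[LabeledCandidate] = []
    for category, records in sorted(rna_groups.items()):
        for rec in records:
            try:
                (_, _), center = find_terminal_loop(fold(rec, engine=engine))
            except NoHairpinError:
                logger.warning("negative %s skipped: no hairpin loop", rec.id)
                continue
            try:
                cand = make_candidate({rec.id: rec}, rec.id, center, engine=engine)
            except (BoundsError, FastaFormatError) as exc:
                logger.warning("negative %s skipped: %s", rec.id, exc)
                continue
            cand = dataclasses.replace(cand, category=category)
            out.append(LabeledCandidate(cand, label=0, source_id=rec.id,
                                        category=category))
    return out


def _dedupe(items: list[LabeledCandidate]) -> list[LabeledCandidate]:
    seen: set[str] = set()
    out = []
    for it in items:
        seq = it.candidate.record.sequence
        if seq not in seen:
            seen.add(seq)
            out.append(it)
    return out


def split_balanced(
    pos: list[LabeledCandidate],
    neg: list[LabeledCandidate],
    neg_quotas: dict[str, int] | None = None,
    test_fraction: float = 0.5,
    seed: int = 0,
    identity_filter: bool = False,
    identity_threshold: float = 0.80,
) -> tuple[list[LabeledCandidate], list[LabeledCandidate]]:
    """Seeded train/test split with per-category negative quotas.

    Exact-duplicate sequences are removed before splitting, so no sequence
    string can occur in both halves.  ``neg_quotas`` fixes how many
    negatives of each category enter the pooled set (error on shortfall,
    listing it).  The optional identity filter additionally drops test
    items whose sequence is >= ``identity_threshold`` similar to any
    training item — a bias check, off by default."""
    rng = np.random.default_rng(seed)
    pos = _dedupe(pos)
    neg = _dedupe(neg)
    if neg_quotas is not None:
        by_cat: dict[str, list[LabeledCandidate]] = {}
        for it in neg:
            by_cat.setdefault(it.category or "?", []).append(it)
        shortfalls = {
            cat: (want, len(by_cat.get(cat, [])))
            for cat, want in neg_quotas.items()
            if len(by_cat.get(cat, [])) < want
        }
        if shortfalls:
            detail = ", ".join(
                f"{cat}: need {want} have {have}"
                for cat, (want, have) in sorted(shortfalls.items())
            )
            raise QuotaError(f"unsatisfiable negative quotas ({detail})")
        chosen: list[LabeledCandidate] = []
        for cat, want in sorted(neg_quotas.items()):
            pool = by_cat[cat]
            idx = rng.choice(len(pool), size=want, replace=False)
            chosen.extend(pool[i] for i in sorted(idx))
        neg = chosen

    def split(items: list[LabeledCandidate]):
        idx = rng.permutation(len(items))
        n_test = int(round(test_fraction * len(items)))
        test_idx = set(idx[:n_test].tolist())
        tr = [items[i] for i in range(len(items)) if i not in test_idx]
        te = [items[i] for i in range(len(items)) if i in test_idx]
        return tr, te

    train_p, test_p = split(pos)
    train_n, test_n = split(neg)
    train = train_p + train_n
    test = test_p + test_n
    if identity_filter:
        kept = []
        train_seqs = [t.candidate.record.sequence for t in train]
        for it in test:
            s = it.candidate.record.sequence
            close = any(
                difflib.SequenceMatcher(None, s, t).ratio() >= identity_threshold
                for t in train_seqs
            )
            if close:
                logger.info("test %s removed by identity filter", it.source_id)
            else:
                kept.append(it)
        test = kept
    return train, test
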