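"""Secondary-structure prediction, terminal-loop location and candidate
windows.

Candidates are always 200 nt with the central base of the dominant terminal
loop at 0-based index 99.  200 is even, so perfect centering is impossible:
the convention here puts 99 bases left of the reference base and 100 right
of it, which fixes the 80/80 left/right window decomposition downstream.

The default folding engine is the ViennaRNA MFE folder (RNAfold) at 37 C
through its Python bindings.  A Nussinov-style maximum-pairing fallback
(minimum loop 3, lone pairs removed) is provided for environments without
the bindings; structures it produces are flagged via ``DotBracket.method``.
"""

from __future__ import annotations

import dataclasses
import functools

import numpy as np

from .seqio import (
    BoundsError,
    FastaFormatError,
    GenomicInterval,
    SequenceRecord,
)

try:  # ViennaRNA Python bindings
    import RNA as _vienna
except ImportError:  # pragma: no cover
    _vienna = None

CANDIDATE_LEN = 200
REF_INDEX = 99  # 0-based position of the loop-center base in the window

MIN_LOOP = 3


class FoldError(RuntimeError):
    """The folding engine failed or was given an unfoldable input."""


class NoHairpinError(ValueError):
    """Structure contains no hairpin loop."""


@dataclasses.dataclass(frozen=True)
class DotBracket:
    """Dot-bracket secondary structure, optionally with its MFE."""

    structure: str
    mfe: float | None = None
    method: str = "vienna"

    def __post_init__(self) -> None:
        depth = 0
        for ch in self.structure:
            if ch == "(":
                depth += 1
            elif ch == ")":
                depth -= 1
                if depth < 0:
                    raise ValueError("unbalanced dot-bracket string")
            elif ch != ".":
                raise ValueError(f"invalid structure character {ch!r}")
        if depth != 0:
            raise ValueError("unbalanced dot-bracket string")

    def __len__(self) -> int:
        return len(self.structure)

    def pair_table(self) -> np.ndarray:
        """partner[i] = index paired with i, or -1 if unpaired."""
        partner = np.full(len(self.structure), -1, dtype=np.int64)
        stack: list[int] = []
        for i, ch in enumerate(self.structure):
            if ch == "(":
                stack.append(i)
            elif ch == ")":
                j = stack.pop()
                partner[i], partner[j] = j, i
        return partner

    @property
    def n_pairs(self) -> int:
        return self.structure.count("(")


@dataclasses.dataclass(frozen=True)
class HairpinCandidate:
    """A 200-nt loop-centered window: sequence, structure, provenance."""

    record: SequenceRecord
    structure: DotBracket
    ref_pos: int = REF_INDEX
    origin: GenomicInterval | None = None
    mature: tuple[int, int] | None = None  # window coordinates, half-open
    category: str | None = None  # negative-source tag (r/sno/sn/t/SINE/ps)

    def __post_init__(self) -> None:
        if len(self.record) != CANDIDATE_LEN:
            raise ValueError(f"candidate must be {CANDIDATE_LEN} nt")
        if len(self.structure) != CANDIDATE_LEN:
            raise ValueError("structure/sequence length mismatch")
        if not (0 <= self.ref_pos < CANDIDATE_LEN):
            raise ValueError("ref_pos outside the window")


def _nussinov(seq: str) -> str:
    """Maximum base-pairing DP with minimum loop length 3; isolated pairs
    are removed afterwards so only >=2-pair stems remain."""
    n = len(seq)
    can_pair = {
        ("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G"),
    }
    dp = np.zeros((n + 1, n + 1), dtype=np.int64)
    for span in range(MIN_LOOP + 1, n):
        for i in range(0, n - span):
            j = i + span
            best = dp[i + 1][j]
            for k in range(i + MIN_LOOP + 1, j + 1):
                if (seq[i], seq[k]) in can_pair:
                    cand = 1 + dp[i + 1][k - 1] + (dp[k + 1][j] if k < j else 0)
                    if cand > best:
                        best = cand
            dp[i][j] = best
    # traceback
    struct = ["."] * n
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if i >= j:
            continue
        if dp[i][j] == dp[i + 1][j]:
            stack.append((i + 1, j))
            continue
        for k in range(i + MIN_LOOP + 1, j + 1):
            if (seq[i], seq[k]) in can_pair:
                if dp[i][j] == 1 + dp[i + 1][k - 1] + (dp[k + 1][j] if k < j else 0):
                    struct[i], struct[k] = "(", ")"
                    stack.append((i + 1, k - 1))
                    if k < j:
                        stack.append((k + 1, j))
                    break
    # drop lone pairs (no stacked neighbour)
    db = DotBracket("".join(struct), method="nussinov")
    partner = db.pair_table()
    for i in range(n):
        j = partner[i]
        if j > i:
            stacked_in = i + 1 < n and partner[i + 1] == j - 1
            stacked_out = i > 0 and partner[i - 1] == j + 1
            if not (stacked_in or stacked_out):
                struct[i] = struct[j] = "."
    return "".join(struct)


@functools.lru_cache(maxsize=100_000)
def _fold_cached(seq: str, engine: str) -> DotBracket:
    if engine == "vienna":
        try:
            structure, mfe = _vienna.fold(seq)
        except Exception as exc:  # pragma: no cover
            raise FoldError(f"folding engine failed: {exc}") from exc
        return DotBracket(structure, mfe=float(mfe), method="vienna")
    return DotBracket(_nussinov(seq), mfe=None, method="nussinov")


def fold(seq: SequenceRecord | str, engine: str = "auto") -> DotBracket:
    """Predict the MFE secondary structure of an RNA sequence.

    ``engine`` is ``"vienna"``, ``"nussinov"`` or ``"auto"`` (ViennaRNA when
    its bindings import, otherwise the fallback).
    """
    s = seq.sequence if isinstance(seq, SequenceRecord) else seq
    if not s:
        raise FoldError("cannot fold an empty sequence")
    if engine == "auto":
        engine = "vienna" if _vienna is not None else "nussinov"
    if engine == "vienna" and _vienna is None:
        raise FoldError("ViennaRNA bindings are not available")
    if engine not in ("vienna", "nussinov"):
        raise ValueError(f"unknown engine {engine!r}")
    return _fold_cached(s, engine)


def find_terminal_loop(db: DotBracket) -> tuple[tuple[int, int], int]:
    """Locate the terminal loop of the dominant hairpin.

    A hairpin loop is the unpaired run enclosed by an innermost base pair.
    Among several hairpins the one whose enclosing stem holds the most base
    pairs wins; ties go to the leftmost.  Returns ``((start, end), center)``
    with the center at the left of the two middle bases for even loops.
    """
    partner = db.pair_table()
    pairs = [(i, int(partner[i])) for i in range(len(db)) if partner[i] > i]
    loops: list[tuple[int, int, int]] = []  # (stem_pairs, start, end)
    for p, q in pairs:
        if all(partner[k] == -1 for k in range(p + 1, q)):
            # innermost pair: hairpin loop is (p, q) exclusive
            stem = sum(1 for a, b in pairs if a <= p and b >= q)
            loops.append((stem, p + 1, q))
    if not loops:
        raise NoHairpinError("structure contains no hairpin loop")
    stem, start, end = max(loops, key=lambda t: (t[0], -t[1]))
    center = start + (end - start - 1) // 2
    return (start, end), center


def make_candidate(
    genome: dict[str, SequenceRecord] | list[SequenceRecord],
    seq_id: str,
    center: int,
    strand: str = "+",
    engine: str = "auto",
) -> HairpinCandidate:
    """Cut the 200-nt window that places forward-strand position ``center``
    at window index 99, refold it, and return the candidate.

    For minus-strand candidates the window is taken symmetrically around the
    same genomic base and reverse-complemented, so the reference base again
    sits at index 99 of the returned sequence.
    """
    if isinstance(genome, list):
        genome = {r.id: r for r in genome}
    if seq_id not in genome:
        raise BoundsError(f"contig {seq_id!r} not in genome")
    contig = genome[seq_id]
    if strand == "+":
        start, end = center - REF_INDEX, center + (CANDIDATE_LEN - REF_INDEX)
    else:
        start, end = center - (CANDIDATE_LEN - REF_INDEX) + 1, center + REF_INDEX + 1
    if start < 0 or end > len(contig):
        raise BoundsError(
            f"window [{start},{end}) around {seq_id}:{center} exceeds contig"
        )
    iv = GenomicInterval(seq_id, start, end, strand)
    from .seqio import extract_interval  # local to avoid cycle at import time

    rec = extract_interval(genome, iv)
    if "N" in rec.sequence:
        raise FastaFormatError(f"candidate window {rec.id} contains N")
    db = fold(rec, engine=engine)
    return HairpinCandidate(record=rec, structure=db, ref_pos=REF_INDEX, origin=iv)
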