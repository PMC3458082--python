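"""Mature-anchored structural profile matrices.

Precursor hairpins are structurally most conserved around the mature-miRNA
arm.  This module exploits that: encoded structures (see
:mod:`premirna.encoding`) are aligned anchored at the mature region —
mature-vs-mature first, then each flank extended outward from the anchor —
clustered at an identity threshold, progressively multiple-aligned, and
condensed into per-column state-probability matrices.  A candidate
structure is then scored by sliding each profile (window length = profile
length) along its plain dot-bracket string and averaging, per placement,
the probability mass the profile assigns to the observed 3-state
characters; the maximum over all profiles and placements is the
candidate's profile score in [0, 1].

Scoring parameters: match +1, mismatch 0, linear gap -1 within each
alignment piece.  Clustering is single-linkage at >= 80% identity by
default.  Profiles are trimmed to the column range covered by every
member (the shortest member extent on each side of the anchor), keeping
only fully-aligning, informative columns.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np

from .encoding import EncodedStructure, EncodingError
from .folding import DotBracket

GAP = "-"
STATES = "MONLDR-"
_STATE_INDEX = {s: i for i, s in enumerate(STATES)}
# collapse to the 3-state dot-bracket alphabet: (=0, .=1, )=2
_COLLAPSE = {"M": 0, "L": 0, "O": 1, "D": 1, "N": 2, "R": 2}
_DB_INDEX = {"(": 0, ".": 1, ")": 2}

MATCH, MISMATCH, GAP_SCORE = 1.0, 0.0, -1.0


class ProfileError(ValueError):
    pass


# ---------------------------------------------------------------------------
# pairwise alignment

def _nw(a: str, b: str) -> tuple[str, str]:
    """Needleman-Wunsch with match +1 / mismatch 0 / gap -1 and a
    deterministic traceback preference (diagonal > up > left).

    Rows are filled vectorized: with a linear gap penalty the left-gap
    recurrence max_j(row[j-1] + g) is a prefix running maximum of
    (candidate[j] - g*j), so each row costs O(m) numpy work."""
    n, m = len(a), len(b)
    bv = np.frombuffer(b.encode(), dtype=np.uint8)
    score = np.empty((n + 1, m + 1))
    score[0, :] = GAP_SCORE * np.arange(m + 1)
    offsets = np.arange(1, m + 1) * (-GAP_SCORE)
    for i in range(1, n + 1):
        prev = score[i - 1]
        sub = np.where(bv == ord(a[i - 1]), MATCH, MISMATCH)
        cand = np.maximum(prev[:-1] + sub, prev[1:] + GAP_SCORE)
        first = i * GAP_SCORE
        # running max of (cand[j] - GAP*j), seeded with the j=0 boundary cell
        run = np.maximum.accumulate(np.concatenate(([first], cand + offsets)))
        score[i, 0] = first
        score[i, 1:] = run[1:] - offsets
    ra, rb = [], []
    i, j = n, m
    while i > 0 or j > 0:
        if i > 0 and j > 0 and score[i, j] == score[i - 1, j - 1] + (
            MATCH if a[i - 1] == b[j - 1] else MISMATCH
        ):
            ra.append(a[i - 1]); rb.append(b[j - 1]); i -= 1; j -= 1
        elif i > 0 and score[i, j] == score[i - 1, j] + GAP_SCORE:
            ra.append(a[i - 1]); rb.append(GAP); i -= 1
        else:
            ra.append(GAP); rb.append(b[j - 1]); j -= 1
    return "".join(reversed(ra)), "".join(reversed(rb))


@dataclasses.dataclass(frozen=True)
class PairwiseAlignment:
    aligned_a: str
    aligned_b: str
    identity: float

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ProfileError("aligned strings differ in length")


def _identity(a: str, b: str) -> float:
    matches = sum(1 for x, y in zip(a, b) if x == y and x != GAP)
    return matches / len(a) if a else 0.0


def anchored_align(a: EncodedStructure, b: EncodedStructure) -> PairwiseAlignment:
    """Global alignment in three anchored pieces: mature-vs-mature, then the
    left flanks aligned outward (right ends pinned at the anchor) and the
    right flanks aligned outward (left ends pinned).  No column mixes
    mature and flank characters.  Identity counts matching columns over all
    aligned columns; gap columns never match."""
    for enc in (a, b):
        if enc.mature[1] <= enc.mature[0]:
            raise EncodingError("encoding lacks a mature anchor")
    # the diagonal-first NW traceback pushes tie gaps to the string start,
    # i.e. the outer end of a left flank; right flanks are reversed so
    # their tie gaps land at the outer (3') end instead of the anchor
    la, lb = _nw(a.left_flank, b.left_flank)
    ma, mb = _nw(a.mature_region, b.mature_region)
    ra, rb = _nw(a.right_flank[::-1], b.right_flank[::-1])
    ra, rb = ra[::-1], rb[::-1]
    full_a = la + ma + ra
    full_b = lb + mb + rb
    return PairwiseAlignment(full_a, full_b, _identity(full_a, full_b))


# ---------------------------------------------------------------------------
# clustering

def cluster(
    encodings: Sequence[EncodedStructure], threshold: float = 0.80
) -> list[list[EncodedStructure]]:
    """Single-linkage clusters over pairs with identity >= threshold.
    Output clusters are ordered by (then within) the input order of their
    first member, which makes the result invariant to input permutation up
    to that canonical ordering."""
    if not encodings:
        raise ProfileError("no encodings to cluster")
    order = sorted(range(len(encodings)), key=lambda i: (encodings[i].source_id, encodings[i].text))
    parent = list(range(len(encodings)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for ii in range(len(order)):
        for jj in range(ii + 1, len(order)):
            i, j = order[ii], order[jj]
            if anchored_align(encodings[i], encodings[j]).identity >= threshold:
                parent[find(i)] = find(j)

    groups: dict[int, list[EncodedStructure]] = {}
    for i in order:
        groups.setdefault(find(i), []).append(encodings[i])
    return sorted(groups.values(), key=lambda g: (g[0].source_id, g[0].text))


# ---------------------------------------------------------------------------
# progressive multiple alignment

@dataclasses.dataclass
class Msa:
    """Blockwise multiple alignment: per-row left / mature / right blocks.

    The anchor (mature start) is column ``len(rows_left[0])`` for every
    row by construction."""

    ids: list[str]
    rows_left: list[str]
    rows_mature: list[str]
    rows_right: list[str]

    @property
    def anchor(self) -> int:
        return len(self.rows_left[0]) if self.rows_left else 0

    def row(self, i: int) -> str:
        return self.rows_left[i] + self.rows_mature[i] + self.rows_right[i]

    @property
    def n_columns(self) -> int:
        return len(self.row(0))


def _consensus(rows: list[str]) -> str:
    if not rows or not rows[0]:
        return ""
    cols = []
    for j in range(len(rows[0])):
        counts: dict[str, int] = {}
        for r in rows:
            if r[j] != GAP:
                counts[r[j]] = counts.get(r[j], 0) + 1
        cols.append(max(sorted(counts), key=counts.get) if counts else GAP)
    return "".join(cols)


def _add_to_block(rows: list[str], piece: str, reverse: bool) -> tuple[list[str], str]:
    """Align ``piece`` to the block consensus; gaps opened in the consensus
    are propagated into every existing row."""
    cons = _consensus(rows)
    if reverse:
        ac, ap = _nw(cons[::-1], piece[::-1])
        ac, ap = ac[::-1], ap[::-1]
    else:
        ac, ap = _nw(cons, piece)
    # map aligned-consensus positions back to original columns
    new_rows = ["" for _ in rows]
    new_piece = []
    src = 0
    for k in range(len(ac)):
        if ac[k] == GAP and cons:  # insertion relative to existing block
            for r in range(len(rows)):
                new_rows[r] += GAP
        elif ac[k] == GAP:  # block was empty: all-gap rows
            for r in range(len(rows)):
                new_rows[r] += GAP
        else:
            for r in range(len(rows)):
                new_rows[r] += rows[r][src]
            src += 1
        new_piece.append(ap[k])
    return new_rows, "".join(new_piece)


def progressive_msa(members: Sequence[EncodedStructure]) -> Msa:
    """Anchored progressive multiple alignment of one cluster.

    Members join in decreasing order of their mean pairwise identity to the
    rest of the cluster (ties broken by id), each aligned blockwise to the
    growing alignment so that the mature anchor column is shared by all
    rows."""
    if not members:
        raise ProfileError("empty cluster")
    if len(members) == 1:
        m = members[0]
        return Msa([m.source_id], [m.left_flank], [m.mature_region], [m.right_flank])
    mean_ident = []
    for i, a in enumerate(members):
        idents = [
            anchored_align(a, b).identity for j, b in enumerate(members) if j != i
        ]
        mean_ident.append(sum(idents) / len(idents))
    order = sorted(
        range(len(members)),
        key=lambda i: (-mean_ident[i], members[i].source_id, members[i].text),
    )
    msa = Msa([], [], [], [])
    for idx in order:
        m = members[idx]
        left, new_l = _add_to_block(msa.rows_left, m.left_flank, reverse=False)
        mat, new_m = _add_to_block(msa.rows_mature, m.mature_region, reverse=False)
        right, new_r = _add_to_block(msa.rows_right, m.right_flank, reverse=True)
        msa.rows_left = left + [new_l]
        msa.rows_mature = mat + [new_m]
        msa.rows_right = right + [new_r]
        msa.ids.append(m.source_id)
    return msa


# ---------------------------------------------------------------------------
# profiles

@dataclasses.dataclass
class StructuralProfile:
    """Per-column state-probability matrix anchored at the mature start.

    ``probs`` has one row per column and one column per state in
    ``"MONLDR-"``; every row sums to 1.  ``anchor`` is the index of the
    first mature column after trimming."""

    probs: np.ndarray
    anchor: int
    members: list[str]

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != len(STATES):
            raise ProfileError("probs must be (length, 7)")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-9):
            raise ProfileError("profile columns must sum to 1")
        if not self.members:
            raise ProfileError("profile needs >= 1 member")

    def __len__(self) -> int:
        return self.probs.shape[0]

    def collapsed(self) -> np.ndarray:
        """(length, 3) matrix over "(", ".", ")" — gap mass dropped and the
        remaining mass renormalized.  All-gap columns become zero rows."""
        three = np.zeros((len(self), 3))
        for state, k in _COLLAPSE.items():
            three[:, k] += self.probs[:, _STATE_INDEX[state]]
        totals = three.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(totals > 0, three / totals, 0.0)
        return out


def build_profile(msa: Msa) -> StructuralProfile:
    """Condense an MSA into a profile, trimmed to the column range covered
    by every member (intersection of member extents about the anchor)."""
    n = len(msa.ids)
    rows = [msa.row(i) for i in range(n)]
    firsts, lasts = [], []
    for r in rows:
        nz = [j for j, ch in enumerate(r) if ch != GAP]
        firsts.append(nz[0])
        lasts.append(nz[-1])
    lo, hi = max(firsts), min(lasts) + 1
    if lo >= hi:
        raise ProfileError("member extents do not intersect")
    probs = np.zeros((hi - lo, len(STATES)))
    for r in rows:
        for j in range(lo, hi):
            probs[j - lo, _STATE_INDEX[r[j]]] += 1.0
    probs /= n
    return StructuralProfile(probs=probs, anchor=msa.anchor - lo, members=list(msa.ids))


@dataclasses.dataclass
class ProfileLibrary:
    profiles: list[StructuralProfile]
    species: str = "synthetic"
    metadata: dict = dataclasses.field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.profiles)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "species": self.species,
            "metadata": self.metadata,
            "states": STATES,
            "profiles": [
                {
                    "anchor": p.anchor,
                    "members": p.members,
                    "probs": p.probs.tolist(),
                }
                for p in self.profiles
            ],
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "ProfileLibrary":
        payload = json.loads(Path(path).read_text())
        if payload.get("states") != STATES:
            raise ProfileError("library was built with a different state order")
        profiles = [
            StructuralProfile(
                probs=np.array(p["probs"]), anchor=p["anchor"], members=p["members"]
            )
            for p in payload["profiles"]
        ]
        return cls(profiles=profiles, species=payload.get("species", ""),
                   metadata=payload.get("metadata", {}))


def build_library(
    encodings: Sequence[EncodedStructure],
    threshold: float = 0.80,
    species: str = "synthetic",
) -> ProfileLibrary:
    """Full pipeline: cluster at the identity threshold, multiple-align each
    cluster anchored at the mature region, and emit one profile per
    cluster."""
    clusters = cluster(encodings, threshold=threshold)
    profiles = [build_profile(progressive_msa(c)) for c in clusters]
    return ProfileLibrary(
        profiles=profiles,
        species=species,
        metadata={"identity_threshold": threshold, "n_input": len(encodings)},
    )


def scan(library: ProfileLibrary, db: DotBracket | str) -> float:
    """Best profile score of a candidate structure in [0, 1].

    Each profile slides a window of its own length along the dot-bracket
    string; a placement scores the mean, over profile columns, of the
    probability mass on the candidate's character (profile states collapsed
    to the 3-letter alphabet).  Profiles longer than the candidate are
    skipped; if every profile is skipped this is an error."""
    if not library.profiles:
        raise ProfileError("empty profile library")
    s = db.structure if isinstance(db, DotBracket) else db
    idx = np.fromiter((_DB_INDEX[ch] for ch in s), dtype=np.int64, count=len(s))
    best = None
    for profile in library.profiles:
        L = len(profile)
        if L > len(s):
            continue
        C = profile.collapsed()  # (L, 3)
        windows = np.lib.stride_tricks.sliding_window_view(idx, L)  # (n-L+1, L)
        picked = C[np.arange(L)[None, :], windows]  # (n-L+1, L)
        score = float(picked.mean(axis=1).max())
        best = score if best is None else max(best, score)
    if best is None:
        raise ProfileError("every profile is longer than the candidate")
    return best
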