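"""Position-aware feature extraction for 200-nt hairpin candidates.

Every candidate is described by 6,622 values laid out as::

    [80 left windows x 40] [1 fixed window x 40] [80 right windows x 40]
    [180 hydrogen-bond values] [CPB] [profile score]

Sliding windows are 21 nt wide and advance 1 nt per step.  The left
windows tile positions [0, 100) (start offsets 0..79), the right windows
tile [100, 200) (offsets 100..179) and the fixed window spans [89, 110),
centered on the loop-reference base at index 99.  Each window contributes
40 densities: 4 mononucleotide (denominator 21), 16 dinucleotide
(denominator 20) and 20 structural-triplet densities (denominator 19) —
the 20 triplets being every length-3 string over "(", ".", ")" in which no
")" precedes a "(", the only triplets realizable inside one hairpin.

The 180-value block gives, for each of the 180 full-sequence windows, the
mean per-position hydrogen-bond weight: G-C pairs weigh 3 bonds, A-U and
G-U wobble pairs 2, unpaired positions 0, with the pairing partner read
from the global dot-bracket.  The final two values are the maximum run of
consecutive paired bases (CPB) and the structural-profile score in [0, 1].
"""

from __future__ import annotations

import itertools

import numpy as np

from .folding import CANDIDATE_LEN, DotBracket, HairpinCandidate
from .seqio import FastaFormatError

WINDOW = 21
N_LEFT = 80
N_RIGHT = 80
N_HBOND = CANDIDATE_LEN - WINDOW + 1  # 180
FIXED_START = 89  # fixed window [89, 110) centered on index 99
N_FEATURES = (N_LEFT + 1 + N_RIGHT) * 40 + N_HBOND + 2  # 6,622

_BASES = "ACGU"
_DINUCS = ["".join(p) for p in itertools.product(_BASES, repeat=2)]

_BOND_WEIGHT = {
    frozenset(("G", "C")): 3.0,
    frozenset(("A", "U")): 2.0,
    frozenset(("G", "U")): 2.0,
}


def triplet_states() -> list[str]:
    """The 20 structural triplets over "(", ".", ")" in which no ")" occurs
    before a "(" — the only triplets a single hairpin can produce — in a
    fixed sorted order."""
    valid = []
    for t in itertools.product("(.)", repeat=3):
        s = "".join(t)
        if not any(a == ")" and b == "(" for a, b in itertools.combinations(s, 2)):
            valid.append(s)
    return sorted(valid)


TRIPLET_STATES = triplet_states()
_TRIPLET_INDEX = {t: i for i, t in enumerate(TRIPLET_STATES)}


def window_features(seq21: str, db21: str) -> np.ndarray:
    """40 densities for one 21-nt window: 4 mono + 16 di + 20 triplet."""
    if len(seq21) != WINDOW or len(db21) != WINDOW:
        raise ValueError(f"window inputs must be {WINDOW} nt")
    if "N" in seq21:
        raise FastaFormatError("window contains N")
    out = np.zeros(40)
    for ch in seq21:
        out[_BASES.index(ch)] += 1.0
    out[:4] /= WINDOW
    for i in range(WINDOW - 1):
        out[4 + _DINUCS.index(seq21[i : i + 2])] += 1.0
    out[4:20] /= WINDOW - 1
    # triplets outside the 20-state set can only arise where a window
    # straddles the junction between two hairpins (a ")" before a "(");
    # densities are taken over the realizable slots so the block stays a
    # probability simplex
    n_valid = 0
    for i in range(WINDOW - 2):
        tri = db21[i : i + 3]
        idx = _TRIPLET_INDEX.get(tri)
        if idx is not None:
            out[20 + idx] += 1.0
            n_valid += 1
    if n_valid:
        out[20:] /= n_valid
    return out


def hbond_profile(candidate: HairpinCandidate) -> np.ndarray:
    """Mean hydrogen-bond weight for each of the 180 full-length windows."""
    seq = candidate.record.sequence
    partner = candidate.structure.pair_table()
    bonds = np.zeros(CANDIDATE_LEN)
    for i in range(CANDIDATE_LEN):
        j = partner[i]
        if j >= 0:
            bonds[i] = _BOND_WEIGHT.get(frozenset((seq[i], seq[j])), 0.0)
    csum = np.concatenate(([0.0], np.cumsum(bonds)))
    starts = np.arange(N_HBOND)
    return (csum[starts + WINDOW] - csum[starts]) / WINDOW


def cpb(db: DotBracket | str) -> int:
    """Maximum number of consecutive paired bases: the longest run of
    non-dot characters in the structure."""
    s = db.structure if isinstance(db, DotBracket) else db
    best = run = 0
    for ch in s:
        run = run + 1 if ch != "." else 0
        best = max(best, run)
    return best


def window_starts() -> list[int]:
    """Start offsets of the 161 windows in layout order (left, fixed, right)."""
    return list(range(N_LEFT)) + [FIXED_START] + list(range(100, 100 + N_RIGHT))


def assemble(candidate: HairpinCandidate, profile_score: float) -> np.ndarray:
    """Assemble the full 6,622-value feature vector for one candidate."""
    if not (0.0 <= profile_score <= 1.0):
        raise ValueError("profile_score must lie in [0, 1]")
    seq = candidate.record.sequence
    db = candidate.structure.structure
    blocks = [
        window_features(seq[s : s + WINDOW], db[s : s + WINDOW])
        for s in window_starts()
    ]
    vec = np.concatenate(
        blocks + [hbond_profile(candidate), [float(cpb(candidate.structure))],
                  [profile_score]]
    )
    assert vec.shape == (N_FEATURES,)
    return vec


def feature_names() -> list[str]:
    """Block-qualified names for all 6,622 features, in vector order."""
    names: list[str] = []
    per_window = (
        [f"mono_{b}" for b in _BASES]
        + [f"di_{d}" for d in _DINUCS]
        + [f"tri_{t}" for t in TRIPLET_STATES]
    )
    labels = (
        [f"L{i:02d}" for i in range(N_LEFT)]
        + ["FIX"]
        + [f"R{i:02d}" for i in range(N_RIGHT)]
    )
    for lab in labels:
        names.extend(f"{lab}_{f}" for f in per_window)
    names.extend(f"hbond_{i:03d}" for i in range(N_HBOND))
    names.extend(["cpb", "profile_score"])
    return names
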