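"""Mature-anchored 6-letter structural alphabet.

Dot-bracket characters inside the annotated mature-miRNA interval map to
M/O/N and those in the flanks to L/D/R::

    mature:  "(" -> M    "." -> O    ")" -> N
    flanks:  "(" -> L    "." -> D    ")" -> R

The distinction lets alignments anchor on the mature arm, which is the
structurally most conserved part of a precursor hairpin.
"""

from __future__ import annotations

import dataclasses

from .folding import DotBracket

MATURE_MAP = {"(": "M", ".": "O", ")": "N"}
FLANK_MAP = {"(": "L", ".": "D", ")": "R"}
_DECODE = {"M": "(", "O": ".", "N": ")", "L": "(", "D": ".", "R": ")"}

MATURE_STATES = frozenset("MON")
FLANK_STATES = frozenset("LDR")


class EncodingError(ValueError):
    pass


@dataclasses.dataclass(frozen=True)
class EncodedStructure:
    """6-letter structural string with its mature anchor interval."""

    text: str
    mature: tuple[int, int]  # half-open, within the string
    source_id: str = ""

    def __post_init__(self) -> None:
        s, e = self.mature
        if not (0 <= s < e <= len(self.text)):
            raise EncodingError(f"mature interval {self.mature} out of bounds")
        inside = set(self.text[s:e])
        outside = set(self.text[:s]) | set(self.text[e:])
        if not inside <= MATURE_STATES or not outside <= FLANK_STATES:
            raise EncodingError("mature/flank alphabets are mixed")

    def __len__(self) -> int:
        return len(self.text)

    @property
    def left_flank(self) -> str:
        return self.text[: self.mature[0]]

    @property
    def mature_region(self) -> str:
        return self.text[self.mature[0] : self.mature[1]]

    @property
    def right_flank(self) -> str:
        return self.text[self.mature[1] :]


def encode(db: DotBracket | str, mature: tuple[int, int], source_id: str = "") -> EncodedStructure:
    """Encode a dot-bracket string with a mature anchor interval."""
    s = db.structure if isinstance(db, DotBracket) else db
    start, end = mature
    if not (0 <= start < end <= len(s)):
        raise EncodingError(f"mature interval {mature} out of bounds for length {len(s)}")
    chars = [
        MATURE_MAP[ch] if start <= i < end else FLANK_MAP[ch]
        for i, ch in enumerate(s)
    ]
    return EncodedStructure("".join(chars), (start, end), source_id)


def decode(enc: EncodedStructure | str) -> str:
    """Map an encoded string back to dot-bracket; inverse of :func:`encode`."""
    text = enc.text if isinstance(enc, EncodedStructure) else enc
    try:
        return "".join(_DECODE[ch] for ch in text)
    except KeyError as exc:
        raise EncodingError(f"unknown encoded character {exc.args[0]!r}") from exc
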