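"""Ballesteros-Weinstein coordinate system for class A GPCR transmembrane helices.

Every alignment column in this package is addressed by a Ballesteros-Weinstein
(BW) label ``H.NN``: ``H`` is the transmembrane helix (1-7) and ``NN`` an index
anchored on the helix's most conserved residue (``x.50``).  The alignment spans
fixed per-helix windows covering the membrane-embedded part of each helix,
171 columns in total; loops, termini and helix kinks are outside the model.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterator

__all__ = [
    "BWPosition",
    "TM_BOUNDARIES",
    "POCKET_POSITIONS",
    "parse_bw",
    "enumerate_tm_positions",
    "N_TM_COLUMNS",
]

_BW_RE = re.compile(r"^(\d)\.(\d+)$")


@dataclass(frozen=True, order=True)
class BWPosition:
    """One TM alignment column, e.g. ``BWPosition(3, 32)`` rendered as ``3.32``.

    Ordering is by helix, then index, which is also the column order of the
    alignment.
    """

    helix: int
    index: int

    def __post_init__(self) -> None:
        if not 1 <= self.helix <= 7:
            raise ValueError(f"helix must be in 1..7, got {self.helix}")
        if self.index < 0:
            raise ValueError(f"index must be non-negative, got {self.index}")

    def __str__(self) -> str:
        return f"{self.helix}.{self.index}"

    def __repr__(self) -> str:
        return f"BWPosition({self.helix}, {self.index})"


def parse_bw(label: str) -> BWPosition:
    """Parse a ``"<helix>.<index>"`` label into a :class:`BWPosition`.

    Raises :class:`ValueError` for malformed labels or a helix outside 1..7.
    """
    m = _BW_RE.match(label.strip())
    if m is None:
        raise ValueError(f"malformed Ballesteros-Weinstein label: {label!r}")
    return BWPosition(int(m.group(1)), int(m.group(2)))


#: Inclusive BW index ranges of the membrane-spanning helix windows.
#: Segment lengths are 24, 26, 27, 22, 26, 23, 23 (171 columns in total).
TM_BOUNDARIES: dict[int, tuple[int, int]] = {
    1: (33, 56),
    2: (40, 65),
    3: (25, 51),
    4: (43, 64),
    5: (38, 63),
    6: (37, 59),
    7: (34, 56),
}


def helix_length(helix: int, boundaries: dict[int, tuple[int, int]] | None = None) -> int:
    """Number of alignment columns of one helix window."""
    lo, hi = (boundaries or TM_BOUNDARIES)[helix]
    return hi - lo + 1


def enumerate_tm_positions(
    boundaries: dict[int, tuple[int, int]] | None = None,
) -> list[BWPosition]:
    """All TM alignment columns in helix-then-index order.

    With the default boundaries this yields 171 positions, ``1.33`` first and
    ``7.56`` last.
    """
    boundaries = boundaries or TM_BOUNDARIES
    out: list[BWPosition] = []
    for helix in sorted(boundaries):
        lo, hi = boundaries[helix]
        if hi < lo:
            raise ValueError(f"empty range for helix {helix}: {lo}-{hi}")
        out.extend(BWPosition(helix, i) for i in range(lo, hi + 1))
    return out


TM_POSITIONS: list[BWPosition] = enumerate_tm_positions()
N_TM_COLUMNS: int = len(TM_POSITIONS)

#: Column offset of each position in the 171-column alignment.
POSITION_INDEX: dict[BWPosition, int] = {p: i for i, p in enumerate(TM_POSITIONS)}

#: Half-open column slice of each helix within the 171-column alignment.
HELIX_SLICES: dict[int, tuple[int, int]] = {}
_off = 0
for _h in sorted(TM_BOUNDARIES):
    _L = helix_length(_h)
    HELIX_SLICES[_h] = (_off, _off + _L)
    _off += _L
del _off, _h, _L


def _pocket() -> frozenset[BWPosition]:
    labels = [
        "1.35", "1.39", "1.42", "1.46",
        "2.57", "2.58", "2.61", "2.65",
        "3.28", "3.29", "3.32", "3.33", "3.36",
        "4.56",
        "5.38", "5.39", "5.42", "5.43", "5.46",
        "6.44", "6.48", "6.51", "6.52", "6.55",
        "7.35", "7.39", "7.43", "7.45",
    ]
    return frozenset(parse_bw(s) for s in labels)


#: The 28 TM positions facing the intramembrane cavity in solved class A
#: structures ("the pocket").  All lie inside TM_BOUNDARIES.
POCKET_POSITIONS: frozenset[BWPosition] = _pocket()


def iter_helix_positions(helix: int) -> Iterator[BWPosition]:
    lo, hi = TM_BOUNDARIES[helix]
    for i in range(lo, hi + 1):
        yield BWPosition(helix, i)
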