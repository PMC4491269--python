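"""The putative STP cystine-motif grammar.

A sequential tri-disulfide peptide (STP) carries six motif cysteines
C1..C6 pairing C1-C4, C2-C5, C3-C6. On the primary sequence the motif
shows up as a characteristic spacing pattern: the loop lengths
dC(i,i+1) — the number of residues strictly between consecutive motif
cysteines — have their minimum in the C-terminal half of the motif, and
that minimum is short (at most three residues).

The grammar implemented here, applied to the full cysteine complement
of a chain:

1. fewer than six cysteines -> no motif;
2. find the minimum loop over all consecutive cysteine pairs of the
   chain (ties broken toward the N-terminus);
3. a minimum loop longer than three residues -> no motif;
4. anchor a six-cysteine window so that the minimum-loop pair sits at
   C3-C4 (two cysteines on each side); when fewer than two cysteines
   remain downstream the pair's role shifts up (C4-C5, then C5-C6),
   taking correspondingly more upstream cysteines; when too few
   upstream cysteines exist the role slides down instead;
5. if the anchored window's own minimum loop lies between C1-C2 or
   C2-C3 the motif is disregarded — short N-terminal CXXC/CXC spacing
   is the signature of electron-transport proteins (ferredoxins,
   rubredoxins, iron-sulfur proteins), not of STPs.

Positions are 1-based in all reported output.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

from .sequence_io import PeptideSequence


class RejectReason(enum.Enum):
    NONE = "none"
    FEWER_THAN_SIX_CYSTEINES = "fewer_than_six_cysteines"
    MIN_LOOP_GT_THREE = "min_loop_gt_three"
    MIN_LOOP_IN_FIRST_TWO = "min_loop_in_first_two"
    CANNOT_ANCHOR = "cannot_anchor"


#: Longest allowed minimum cysteine loop for a putative STP motif.
MAX_MIN_LOOP = 3


@dataclass(frozen=True)
class CysteineMotif:
    """An anchored six-cysteine window with its loop geometry.

    ``positions`` are the 1-based indices of C1..C6 (empty or shorter
    when no window could be anchored); ``loops`` are the residue counts
    strictly between consecutive window cysteines; ``min_loop_index``
    is the 0-based index into ``loops`` of the window minimum (pair
    (i+1, i+2) in C-numbering), N-terminal-most on ties.
    """

    positions: tuple[int, ...]
    loops: tuple[int, ...]
    min_loop_index: int | None
    valid: bool
    reject_reason: RejectReason = field(default=RejectReason.NONE)

    @property
    def min_loop(self) -> int | None:
        if self.min_loop_index is None:
            return None
        return self.loops[self.min_loop_index]


def cysteine_positions(seq: PeptideSequence) -> list[int]:
    """1-based positions of every cysteine in the chain."""
    return [i + 1 for i, ch in enumerate(seq.residues) if ch == "C"]


def loop_lengths(positions: list[int]) -> list[int]:
    """Residues strictly between consecutive cysteines: dC(i, i+1)."""
    return [b - a - 1 for a, b in zip(positions, positions[1:])]


def _argmin_nterm(loops: list[int]) -> int:
    """Index of the smallest loop, most N-terminal on ties."""
    best = 0
    for i, v in enumerate(loops):
        if v < loops[best]:
            best = i
    return best


def anchor_motif(positions: list[int]) -> CysteineMotif:
    """Anchor the six-cysteine STP window around the minimum loop.

    ``positions`` must be every cysteine index of one chain, strictly
    increasing. Invalidity is a value (``valid=False`` with a
    ``reject_reason``), never an exception.
    """
    n = len(positions)
    chain_loops = loop_lengths(positions)

    if n < 6:
        return CysteineMotif(
            positions=tuple(positions),
            loops=tuple(chain_loops),
            min_loop_index=_argmin_nterm(chain_loops) if chain_loops else None,
            valid=False,
            reject_reason=RejectReason.FEWER_THAN_SIX_CYSTEINES,
        )

    m = _argmin_nterm(chain_loops)  # global min pair: cysteines m, m+1 (0-based)
    if chain_loops[m] > MAX_MIN_LOOP:
        return CysteineMotif(
            positions=tuple(positions),
            loops=tuple(chain_loops),
            min_loop_index=m,
            valid=False,
            reject_reason=RejectReason.MIN_LOOP_GT_THREE,
        )

    upstream = m                # cysteines strictly before the pair
    downstream = n - m - 2      # cysteines strictly after the pair
    # Role r: the pair occupies window offsets (r, r+1); default C3-C4
    # (r=2). Too few downstream cysteines shifts the role up; too few
    # upstream slides it down. With >= 6 cysteines a window always
    # exists, but the cascade is kept defensive.
    r = min(max(2, 4 - downstream), upstream)
    start = m - r
    if start < 0 or start + 6 > n:  # pragma: no cover - unreachable for n >= 6
        return CysteineMotif(
            positions=tuple(positions),
            loops=tuple(chain_loops),
            min_loop_index=m,
            valid=False,
            reject_reason=RejectReason.CANNOT_ANCHOR,
        )

    window = positions[start : start + 6]
    window_loops = loop_lengths(window)
    w_min = _argmin_nterm(window_loops)

    if w_min in (0, 1):  # ferredoxin/rubredoxin exclusion
        return CysteineMotif(
            positions=tuple(window),
            loops=tuple(window_loops),
            min_loop_index=w_min,
            valid=False,
            reject_reason=RejectReason.MIN_LOOP_IN_FIRST_TWO,
        )

    return CysteineMotif(
        positions=tuple(window),
        loops=tuple(window_loops),
        min_loop_index=w_min,
        valid=True,
        reject_reason=RejectReason.NONE,
    )


def scan(seq: PeptideSequence) -> CysteineMotif:
    """Locate and validate the putative STP motif of one chain."""
    return anchor_motif(cysteine_positions(seq))
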