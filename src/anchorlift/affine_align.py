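"""Global pairwise alignment with affine gap costs (Gotoh three-state DP).

Used to place an anchor base that falls inside a chain gap: the window
around the variant in the source assembly is realigned against the
corresponding destination window, and the failed anchor's position is read
off the optimal alignment.  Alignment is global over the extracted windows
(one end is pinned by the successfully mapped anchor, the other bounded by
the window), not local.

A gap of length L costs ``gap_open + (L - 1) * gap_extend``, i.e. the
opening penalty covers the first gapped base.  Traceback tie-breaking is
deterministic: diagonal (match/mismatch) is preferred, then a gap in the
destination sequence, then a gap in the source, evaluated from the terminal
cell — this biases inferred anchors leftward, consistent with the
left-alignment applied downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

NEG_INF = float(-1e18)


@dataclass(frozen=True)
class AlignmentParams:
    """Scores are additive; penalties are non-positive.

    ``gap_open`` is the total cost of a length-1 gap and must be at least as
    costly as ``gap_extend``.
    """

    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -2.0
    gap_extend: float = -1.0

    def __post_init__(self) -> None:
        if self.match < 0:
            raise ValueError("match score must be >= 0")
        if not (self.gap_open <= self.gap_extend <= 0):
            raise ValueError("require gap_open <= gap_extend <= 0")
        if self.mismatch > 0:
            raise ValueError("mismatch penalty must be <= 0")


@dataclass(frozen=True)
class Alignment:
    """Optimal global alignment as ordered coordinate columns.

    Each column pairs a 1-based position in A (or ``None`` for a gap) with a
    1-based position in B (or ``None``).
    """

    score: float
    columns: tuple[tuple[Optional[int], Optional[int]], ...]

    def rescore(self, a: str, b: str, params: AlignmentParams) -> float:
        """Recompute the score from the columns (consistency check)."""
        total = 0.0
        prev_gap = None  # which side was gapped in the previous column
        for ai, bi in self.columns:
            if ai is not None and bi is not None:
                total += params.match if a[ai - 1] == b[bi - 1] else params.mismatch
                prev_gap = None
            else:
                side = "a" if ai is None else "b"
                total += params.gap_extend if prev_gap == side else params.gap_open
                prev_gap = side
        return total


class AlignmentRefusedError(Exception):
    """Input exceeds the configured length cap."""


def align_global_affine(
    a: str, b: str, params: AlignmentParams = AlignmentParams(),
    max_len: int = 10_000,
) -> Alignment:
    """Optimal global alignment of ``a`` and ``b`` under affine gap costs.

    Three-state DP (match, gap-in-b consuming a, gap-in-a consuming b) with
    full traceback.  Refuses inputs longer than ``max_len``.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    if len(a) > max_len or len(b) > max_len:
        raise AlignmentRefusedError(
            f"sequence length {max(len(a), len(b))} exceeds cap {max_len}")
    n, m = len(a), len(b)
    go, ge = params.gap_open, params.gap_extend
    # M[i][j]: best score of aligning a[:i], b[:j] ending in a diagonal column;
    # X: ending with a gap in b (a[i] consumed); Y: ending with a gap in a.
    M = np.full((n + 1, m + 1), NEG_INF)
    X = np.full((n + 1, m + 1), NEG_INF)
    Y = np.full((n + 1, m + 1), NEG_INF)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = go + (i - 1) * ge
    for j in range(1, m + 1):
        Y[0, j] = go + (j - 1) * ge
    au = a.upper()
    bu = b.upper()
    for i in range(1, n + 1):
        ai = au[i - 1]
        Mi1, Xi1, Yi1 = M[i - 1], X[i - 1], Y[i - 1]
        Mi, Xi, Yi = M[i], X[i], Y[i]
        for j in range(1, m + 1):
            s = params.match if ai == bu[j - 1] else params.mismatch
            Mi[j] = max(Mi1[j - 1], Xi1[j - 1], Yi1[j - 1]) + s
            Xi[j] = max(Mi1[j] + go, Xi1[j] + ge, Yi1[j] + go)
            Yi[j] = max(Mi[j - 1] + go, Yi[j - 1] + ge, Xi[j - 1] + go)

    # traceback from the best terminal state; ties prefer M, then X, then Y
    i, j = n, m
    state = max(("M", "X", "Y"), key=lambda st: {"M": M, "X": X, "Y": Y}[st][n, m])
    # max() with key keeps the first maximal element, so order M, X, Y applies
    score = {"M": M, "X": X, "Y": Y}[state][n, m]
    cols: list[tuple[Optional[int], Optional[int]]] = []
    eps = 1e-9
    while i > 0 or j > 0:
        if state == "M":
            s = params.match if au[i - 1] == bu[j - 1] else params.mismatch
            cols.append((i, j))
            target = M[i, j] - s
            i, j = i - 1, j - 1
            for st, mat in (("M", M), ("X", X), ("Y", Y)):
                if abs(mat[i, j] - target) < eps:
                    state = st
                    break
        elif state == "X":
            cols.append((i, None))
            val = X[i, j]
            i -= 1
            if abs(M[i, j] + go - val) < eps:
                state = "M"
            elif abs(X[i, j] + ge - val) < eps:
                state = "X"
            else:
                state = "Y"
        else:  # Y
            cols.append((None, j))
            val = Y[i, j]
            j -= 1
            if abs(M[i, j] + go - val) < eps:
                state = "M"
            elif abs(Y[i, j] + ge - val) < eps:
                state = "Y"
            else:
                state = "X"
        if i == 0 and j == 0:
            break
        if i == 0 and state != "Y":
            state = "Y"
        if j == 0 and state != "X":
            state = "X"
    cols.reverse()
    return Alignment(score=float(score), columns=tuple(cols))


@dataclass(frozen=True)
class Projection:
    """B-side coordinate aligned to a queried A position."""

    b_pos: Optional[int]
    in_gap: bool


def project_position(aln: Alignment, a_pos: int) -> Projection:
    """Project a 1-based A position onto B through the alignment.

    When ``a_pos`` is aligned to a B base, returns that position with
    ``in_gap=False``.  When it falls in a B gap, returns the nearest
    preceding aligned B position (or ``None`` if there is none) with
    ``in_gap=True``.
    """
    last_b: Optional[int] = None
    for ai, bi in aln.columns:
        if ai == a_pos:
            if bi is not None:
                return Projection(b_pos=bi, in_gap=False)
            return Projection(b_pos=last_b, in_gap=True)
        if bi is not None:
            last_b = bi
    raise ValueError(f"a_pos {a_pos} outside the aligned A sequence")


def infer_missing_anchor(
    src_window: str,
    dst_window: str,
    src_anchor_offset: int,
    params: AlignmentParams = AlignmentParams(),
    max_len: int = 10_000,
) -> Optional[int]:
    """Locate a failed anchor in the destination window by realignment.

    ``src_anchor_offset`` is the 0-based offset of the failed anchor within
    ``src_window``; the windows are extracted by the caller so that the
    successfully mapped anchor sits at the same offset in both.  Returns the
    0-based offset of the anchor within ``dst_window``, or ``None`` when the
    projected column lands inside a gap (low confidence).
    """
    if not 0 <= src_anchor_offset < len(src_window):
        raise ValueError("anchor offset outside the source window")
    aln = align_global_affine(src_window, dst_window, params, max_len=max_len)
    proj = project_position(aln, src_anchor_offset + 1)
    if proj.in_gap or proj.b_pos is None:
        return None
    return proj.b_pos - 1
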