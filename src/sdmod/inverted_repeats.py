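"""Inverted-repeat detection by arm-vs-reverse-complement local alignment.

The finder reproduces the einverted-style search used to nominate sRNA
precursor candidates: match +4, mismatch -4, linear gap -8 per gapped
column, minimum alignment score 50, and total span (left-arm start to
right-arm end) at most 350 nt. Complementarity here is Watson-Crick only;
G:T is a mismatch (wobble pairing enters only in the RNA-context hairpin
evaluation and target scoring).

Algorithmically the sequence is aligned against its own reverse complement
with a Smith-Waterman recurrence restricted to the anti-diagonal band that
the span constraint allows. Because the anti-diagonal index ``i + j`` is
non-decreasing along any alignment path, constraining cells to
``n - max_span <= i + j <= n - 2`` enforces both the span limit and arm
disjointness exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io import Interval, LocusSequence

_ENC = bytes.maketrans(b"ACGTN", bytes([0, 1, 2, 3, 4]))
_BASES = "ACGTN"
_NEG = -(10**6)


@dataclass(frozen=True)
class IRParams:
    """Scoring and span parameters of the inverted-repeat search."""

    match_score: int = 4
    mismatch_score: int = -4
    gap_score: int = -8  # per gapped column, linear
    min_score: int = 50
    max_span: int = 350

    def __post_init__(self) -> None:
        if self.match_score <= 0:
            raise ValueError("match_score must be positive")
        if self.min_score <= 0:
            raise ValueError("min_score must be positive")
        if self.max_span < 2:
            raise ValueError("max_span must be >= 2")
        if self.mismatch_score > 0 or self.gap_score > 0:
            raise ValueError("mismatch_score and gap_score are penalties (<= 0)")


@dataclass(frozen=True)
class InvertedRepeat:
    """Two arms plus their arm-vs-arm alignment.

    ``columns`` pairs left-arm bases with the *original* (not complemented)
    right-arm bases, outermost stem pair first; ``-`` marks a gapped column.
    """

    left_arm: Interval
    right_arm: Interval
    score: int
    columns: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if self.left_arm.end > self.right_arm.start:
            raise ValueError("left arm must end before right arm starts")

    @property
    def loop_len(self) -> int:
        return self.right_arm.start - self.left_arm.end

    @property
    def span(self) -> int:
        return self.right_arm.end - self.left_arm.start


def _pair_matrix(params: IRParams) -> np.ndarray:
    pm = np.full((5, 5), params.mismatch_score, dtype=np.int32)
    for a, b in (("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")):
        pm[_BASES.index(a), _BASES.index(b)] = params.match_score
    return pm


def _encode(s: str) -> np.ndarray:
    return np.frombuffer(s.encode().translate(_ENC), dtype=np.uint8)


def _fill_band(e: np.ndarray, params: IRParams) -> tuple[np.ndarray, int]:
    """Fill the banded DP matrix.

    Returns ``(H, W)`` where ``H[i, k]`` is the best score of a local
    alignment ending with left-arm base ``i`` paired against right-arm base
    ``r = W + i - 1 - k``, and ``W = min(max_span, n)``.
    """
    n = len(e)
    W = min(params.max_span, n)
    B = W - 1
    pm = _pair_matrix(params)
    gap = params.gap_score
    g = -gap
    H = np.zeros((n, B), dtype=np.int32)
    karr = np.arange(B)
    gk = g * karr
    prev = np.zeros(B, dtype=np.int32)
    D = np.zeros(B, dtype=np.int32)
    U = np.zeros(B, dtype=np.int32)
    for i in range(n):
        r = (W + i - 1) - karr
        kmin = W + i - n  # below this, r >= n: no such right-arm base
        rc = np.clip(r, 0, n - 1)
        sc = pm[e[i], e[rc]]
        if kmin > 0:
            sc[:kmin] = _NEG
        D[2:] = prev[:-2]
        D[:2] = 0
        U[1:] = prev[:-1]
        U[0] = 0
        T = np.maximum(0, np.maximum(D + sc, U + gap))
        row = np.maximum.accumulate(T + gk) - gk
        H[i] = row
        prev = row
    return H, W


def _traceback(
    H: np.ndarray, s: str, e: np.ndarray, pm: np.ndarray, gap: int, W: int, i: int, k: int
) -> tuple[int, int, list[tuple[str, str]]]:
    """Walk back from cell (i, k); returns (i_start, j_start, columns end->start)."""
    n = len(s)
    cols: list[tuple[str, str]] = []
    while True:
        j = k + (n - W - i)
        r = n - 1 - j
        val = int(H[i, k])
        sc = int(pm[e[i], e[r]])
        prevd = int(H[i - 1, k - 2]) if (i >= 1 and k >= 2) else 0
        if val == prevd + sc:
            cols.append((s[i], s[r]))
            if i >= 1 and k >= 2 and prevd > 0:
                i, k = i - 1, k - 2
                continue
            return i, j, cols
        if i >= 1 and k >= 1 and val == int(H[i - 1, k - 1]) + gap:
            cols.append((s[i], "-"))
            i, k = i - 1, k - 1
            continue
        if k >= 1 and val == int(H[i, k - 1]) + gap:
            cols.append(("-", s[r]))
            k = k - 1
            continue
        raise AssertionError("traceback failed: inconsistent DP matrix")


def align_arms(
    seq: LocusSequence, left: Interval, right: Interval, params: IRParams = IRParams()
) -> InvertedRepeat:
    """Rebuild an :class:`InvertedRepeat` from known arm coordinates by global
    alignment of the left arm against the reverse complement of the right arm
    (used when arms come from a GFF3 file rather than a fresh search)."""
    a = seq.subseq(left.start, left.end)
    b_rev = seq.subseq(right.start, right.end)[::-1]  # WC pairing is scored column-wise
    la, lb = len(a), len(b_rev)
    pm = _pair_matrix(params)
    ea, eb = _encode(a), _encode(b_rev)
    gap = params.gap_score
    H = np.zeros((la + 1, lb + 1), dtype=np.int64)
    H[0, :] = gap * np.arange(lb + 1)
    H[:, 0] = gap * np.arange(la + 1)
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            H[i, j] = max(
                H[i - 1, j - 1] + pm[ea[i - 1], eb[j - 1]],
                H[i - 1, j] + gap,
                H[i, j - 1] + gap,
            )
    cols: list[tuple[str, str]] = []
    i, j = la, lb
    while i > 0 or j > 0:
        if i > 0 and j > 0 and H[i, j] == H[i - 1, j - 1] + pm[ea[i - 1], eb[j - 1]]:
            cols.append((a[i - 1], b_rev[j - 1]))
            i, j = i - 1, j - 1
        elif i > 0 and H[i, j] == H[i - 1, j] + gap:
            cols.append((a[i - 1], "-"))
            i -= 1
        else:
            cols.append(("-", b_rev[j - 1]))
            j -= 1
    cols.reverse()
    return InvertedRepeat(left, right, int(H[la, lb]), tuple(cols))


def resolve_overlaps(cands: Sequence[InvertedRepeat], n: int) -> list[InvertedRepeat]:
    """Greedy overlap resolution: keep the highest-scoring IR per overlapping
    arm-footprint cluster; ties broken by smaller span, then leftmost arms."""
    ordered = sorted(
        cands, key=lambda ir: (-ir.score, ir.span, ir.left_arm.start, ir.right_arm.start)
    )
    occupied = np.zeros(n, dtype=bool)
    accepted: list[InvertedRepeat] = []
    for ir in ordered:
        la, ra = ir.left_arm, ir.right_arm
        if occupied[la.start : la.end].any() or occupied[ra.start : ra.end].any():
            continue
        occupied[la.start : la.end] = True
        occupied[ra.start : ra.end] = True
        accepted.append(ir)
    accepted.sort(key=lambda ir: (ir.left_arm.start, -ir.score, ir.right_arm.start))
    return accepted


def find_inverted_repeats(seq: LocusSequence, params: IRParams = IRParams()) -> list[InvertedRepeat]:
    """Report all local-maximum inverted repeats satisfying the score and span rules.

    Output is deterministic, ordered by (left arm start, score descending).
    """
    s = seq.residues
    n = len(s)
    if n < 2:
        raise ValueError("sequence must have length >= 2")
    H, W = _fill_band(_encode(s), params)
    if W < 2:
        return []
    e = _encode(s)
    pm = _pair_matrix(params)
    hits_i, hits_k = np.nonzero(H >= params.min_score)
    if len(hits_i) == 0:
        return []
    # path-dominance pruning: skip cells whose diagonal successor scores at
    # least as high -- their alignment extends to a better one ending later.
    succ = np.zeros(len(hits_i), dtype=bool)
    ok_idx = (hits_i + 1 < H.shape[0]) & (hits_k + 2 < H.shape[1])
    succ[ok_idx] = (
        H[hits_i[ok_idx] + 1, hits_k[ok_idx] + 2] >= H[hits_i[ok_idx], hits_k[ok_idx]]
    )
    cands: list[InvertedRepeat] = []
    for i, k in zip(hits_i[~succ], hits_k[~succ]):
        i = int(i)
        k = int(k)
        i0, j0, cols = _traceback(H, s, e, pm, params.gap_score, W, i, k)
        j_end = k + (n - W - i)
        cols.reverse()
        left = Interval(seq.id, i0, i + 1)
        right = Interval(seq.id, n - 1 - j_end, n - j0)
        cands.append(InvertedRepeat(left, right, int(H[i, k]), tuple(cols)))
    return resolve_overlaps(cands, n)
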