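"""Independent brute-force reference implementations used only by the tests.

Everything here is deliberately written as slow, transparent pure Python
(dicts, nested loops, no numpy, no banding) so that agreement with the
package's vectorized implementations is a meaningful check.
"""

from __future__ import annotations

from sdmod.inverted_repeats import IRParams
from sdmod.targets import WobbleScoreScheme

_WC = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}


def _pair_score(a: str, b: str, params: IRParams) -> int:
    if (a, b) in _WC:
        return params.match_score
    return params.mismatch_score


# ---------------------------------------------------------------------------
# Inverted repeats: full-matrix local alignment of s against revcomp(s) with
# the span/arm-disjointness constraints expressed directly on cell validity.


def oracle_find_irs(s: str, params: IRParams) -> list[tuple[int, int, int, int, int]]:
    """All overlap-resolved inverted repeats as (l0, l1, r0, r1, score)."""
    n = len(s)
    comp = {"A": "T", "T": "A", "G": "C", "C": "G", "N": "N"}
    rc = "".join(comp[c] for c in reversed(s))
    W = min(params.max_span, n)
    lo, hi = n - W, n - 2
    gap = params.gap_score

    H: dict[tuple[int, int], int] = {}

    def get(i: int, j: int) -> int:
        return H.get((i, j), 0)

    def cell_score(i: int, j: int) -> int:
        a, b = s[i], rc[j]
        return params.match_score if a == b and a != "N" else params.mismatch_score

    for i in range(n):
        for j in range(n):
            if not (lo <= i + j <= hi):
                continue
            H[(i, j)] = max(
                0,
                get(i - 1, j - 1) + cell_score(i, j),
                get(i - 1, j) + gap,
                get(i, j - 1) + gap,
            )

    def traceback(i: int, j: int):
        cols = 0
        while True:
            val = get(i, j)
            prevd = get(i - 1, j - 1)
            if val == prevd + cell_score(i, j):
                cols += 1
                if prevd > 0 and lo <= (i - 1) + (j - 1) <= hi and i >= 1 and j >= 1:
                    i, j = i - 1, j - 1
                    continue
                return i, j
            if val == get(i - 1, j) + gap:
                i -= 1
                continue
            if val == get(i, j - 1) + gap:
                j -= 1
                continue
            raise AssertionError("oracle traceback failed")

    cands = []
    for (i, j), val in H.items():
        if val < params.min_score:
            continue
        succ = H.get((i + 1, j + 1))
        if succ is not None and succ >= val:
            continue
        i0, j0 = traceback(i, j)
        left = (i0, i + 1)
        right = (n - 1 - j, n - j0)
        span = right[1] - left[0]
        cands.append((val, span, left, right))

    cands.sort(key=lambda c: (-c[0], c[1], c[2][0], c[3][0]))
    occupied = [False] * n
    out = []
    for score, _span, left, right in cands:
        cells = list(range(*left)) + list(range(*right))
        if any(occupied[p] for p in cells):
            continue
        for p in cells:
            occupied[p] = True
        out.append((left[0], left[1], right[0], right[1], score))
    out.sort(key=lambda t: (t[0], -t[4], t[2]))
    return out


# ---------------------------------------------------------------------------
# Inverted repeats: literal arm-pair enumeration (Needleman-Wunsch global
# score of every left-arm/right-arm interval pair under the same scoring).


def _nw_global(a: str, b: str, params: IRParams) -> int:
    la, lb = len(a), len(b)
    gap = params.gap_score
    prev = [gap * j for j in range(lb + 1)]
    for i in range(1, la + 1):
        cur = [gap * i] + [0] * lb
        for j in range(1, lb + 1):
            cur[j] = max(
                prev[j - 1] + _pair_score(a[i - 1], b[j - 1], params),
                prev[j] + gap,
                cur[j - 1] + gap,
            )
        prev = cur
    return prev[lb]


def enumerate_best_ir(s: str, params: IRParams):
    """(best score, set of argmax (l0, l1, r0, r1)) over every arm pair.

    The left arm is aligned against the right arm read right-to-left, with a
    column scoring as a match iff the two bases Watson-Crick pair.
    """
    n = len(s)
    best = None
    argmax = set()
    for l0 in range(n):
        for l1 in range(l0 + 1, n + 1):
            for r0 in range(l1, n):
                for r1 in range(r0 + 1, n + 1):
                    if r1 - l0 > params.max_span:
                        continue
                    score = _nw_global(s[l0:l1], s[r0:r1][::-1], params)
                    if best is None or score > best:
                        best = score
                        argmax = {(l0, l1, r0, r1)}
                    elif score == best:
                        argmax.add((l0, l1, r0, r1))
    return best, argmax


# ---------------------------------------------------------------------------
# Wobble target scanning: pure-Python local alignment in doubled units over a
# duplex-comparison string (reverse complement of the targeted transcript).


def _duplex_score_x2(q: str, t: str, scheme: WobbleScoreScheme) -> int:
    m2, x2, _g2, w2, _c2 = scheme.x2
    if "N" in (q, t):
        return x2
    if q == t:
        return m2
    if (q, t) in (("G", "A"), ("T", "C")):
        return w2
    return x2


def oracle_scan_strand(srna: str, comp_chars: str, scheme: WobbleScoreScheme):
    """Overlap-resolved local optima as (score_x2, start, end) tuples."""
    m, n = len(srna), len(comp_chars)
    g2 = scheme.x2[2]
    cut2 = scheme.x2[4] + (1 if scheme.strict_cutoff else 0)
    H = [[0] * n for _ in range(m)]
    for i in range(m):
        for j in range(n):
            diag = H[i - 1][j - 1] if i and j else 0
            up = H[i - 1][j] if i else 0
            left = H[i][j - 1] if j else 0
            H[i][j] = max(0, diag + _duplex_score_x2(srna[i], comp_chars[j], scheme), up + g2, left + g2)
    cands = []
    for i in range(m):
        for j in range(n):
            val = H[i][j]
            if val < cut2:
                continue
            if i + 1 < m and j + 1 < n and H[i + 1][j + 1] >= val:
                continue
            ii, jj, gaps = i, j, 0
            while True:
                v = H[ii][jj]
                diag = H[ii - 1][jj - 1] if ii and jj else 0
                if v == diag + _duplex_score_x2(srna[ii], comp_chars[jj], scheme):
                    if ii and jj and diag > 0:
                        ii, jj = ii - 1, jj - 1
                        continue
                    break
                if ii and v == H[ii - 1][jj] + g2:
                    gaps += 1
                    ii -= 1
                    continue
                if jj and v == H[ii][jj - 1] + g2:
                    gaps += 1
                    jj -= 1
                    continue
                raise AssertionError("oracle traceback failed")
            cands.append((val, gaps, jj, j + 1))
    cands.sort(key=lambda c: (-c[0], c[1], c[2], c[3]))
    taken = [False] * n
    out = []
    for score, _gaps, start, end in cands:
        if any(taken[start:end]):
            continue
        for p in range(start, end):
            taken[p] = True
        out.append((score, start, end))
    out.sort(key=lambda c: c[1])
    return out


def enumerate_best_duplex_x2(srna: str, comp_chars: str, scheme: WobbleScoreScheme, max_gaps: int = 2) -> int:
    """Best doubled score over all start positions x all monotone alignments
    with at most ``max_gaps`` gap columns (free start and end on both sides)."""
    m, n = len(srna), len(comp_chars)
    g2 = scheme.x2[2]
    best = 0

    def go(i: int, j: int, score: int, gaps_left: int) -> None:
        nonlocal best
        if score > best:
            best = score
        if i < m and j < n:
            go(i + 1, j + 1, score + _duplex_score_x2(srna[i], comp_chars[j], scheme), gaps_left)
        if gaps_left:
            if i < m:
                go(i + 1, j, score + g2, gaps_left - 1)
            if j < n:
                go(i, j + 1, score + g2, gaps_left - 1)

    for i0 in range(m):
        for j0 in range(n):
            go(i0, j0, 0, max_gaps)
    return best


# ---------------------------------------------------------------------------
# Small-RNA mapping: naive full scan.


def naive_placements(read: str, refs: dict[str, str]) -> list[tuple[str, int, str]]:
    comp = {"A": "T", "T": "A", "G": "C", "C": "G", "N": "N"}
    rc = "".join(comp[c] for c in reversed(read))
    out = []
    for sid, ref in refs.items():
        for strand, query in (("+", read), ("-", rc)):
            if "N" in query:
                continue
            for p in range(len(ref) - len(query) + 1):
                window = ref[p : p + len(query)]
                if window == query and "N" not in window:
                    out.append((sid, p, strand))
    return sorted(out)


# ---------------------------------------------------------------------------
# Diversity: direct double loop over all pairs and columns.


def naive_diversity(rows: list[str]) -> tuple[float, float, int, int]:
    n = len(rows)
    L = len(rows[0])
    usable = [c for c in range(L) if all(rows[i][c] in "ACGT" for i in range(n))]
    L_used = len(usable)
    S = sum(1 for c in usable if len({rows[i][c] for i in range(n)}) > 1)
    diffs = 0
    pairs = 0
    for i in range(n):
        for j in range(i + 1, n):
            pairs += 1
            diffs += sum(1 for c in usable if rows[i][c] != rows[j][c])
    pi = diffs / (pairs * L_used)
    a_n = sum(1.0 / i for i in range(1, n))
    return pi, S / (a_n * L_used), S, L_used
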