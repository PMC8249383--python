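"""sRNA-target affinity scoring with G:U-wobble-aware local alignment.

The scorer is a modified Smith-Waterman over the hybridized duplex: the sRNA
(5'->3') is aligned against the target transcript read 3'->5', with

* match (Watson-Crick pair)  +1
* G:U wobble                 -0.5
* mismatch                   -1
* gap (either duplex strand) -2 per gapped column

and a hit cutoff of 18. Scores are half-integers and are accumulated in
doubled integer units so cutoff comparisons are exact. Both target strands
are scanned; a hit on strand ``s`` means the sRNA hybridizes the strand-``s``
transcript. N never matches, pairs or wobbles.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io import Interval, LocusSequence, WC_PAIRS, revcomp

_ENC = bytes.maketrans(b"ACGTN", bytes([0, 1, 2, 3, 4]))
_BASES = "ACGTN"

#: pairing-string codes
MATCH, WOBBLE, MISMATCH, GAP = "=", "w", "x", "-"


@dataclass(frozen=True)
class WobbleScoreScheme:
    """Duplex scoring terms (in score units; halves allowed) and the hit cutoff."""

    match: float = 1.0
    mismatch: float = -1.0
    gap: float = -2.0
    wobble: float = -0.5
    cutoff: float = 18.0
    # Methods say "cutoff ... of 18", Results say "affinity >18"; >= is the
    # default and the comparator is configurable.
    strict_cutoff: bool = False

    def __post_init__(self) -> None:
        if self.match <= 0:
            raise ValueError("match must be positive")
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        for name in ("match", "mismatch", "gap", "wobble", "cutoff"):
            if (2 * getattr(self, name)) != int(2 * getattr(self, name)):
                raise ValueError(f"{name} must be a half-integer for exact arithmetic")

    @property
    def x2(self) -> tuple[int, int, int, int, int]:
        return (
            int(2 * self.match),
            int(2 * self.mismatch),
            int(2 * self.gap),
            int(2 * self.wobble),
            int(2 * self.cutoff),
        )


@dataclass(frozen=True)
class TargetHit:
    srna_id: str
    target: Interval  # strand = targeted transcript strand
    score_x2: int
    pairing_string: str  # per sRNA 5'->3' column: '=' match, 'w' wobble, 'x' mismatch, '-' gap

    @property
    def score(self) -> float:
        return self.score_x2 / 2

    @property
    def n_gaps(self) -> int:
        return self.pairing_string.count(GAP)


def pair_class(srna_base: str, target_base: str) -> str:
    """Classify a duplex base pair: 'match' (Watson-Crick), 'wobble' (G:U,
    i.e. (G,T) or (T,G) on the T-normalized alphabet) or 'mismatch'."""
    for b in (srna_base, target_base):
        if b not in "ACGTN":
            raise ValueError(f"invalid nucleotide {b!r}")
    if "N" in (srna_base, target_base):
        return "mismatch"
    if (srna_base, target_base) in WC_PAIRS:
        return "match"
    if (srna_base, target_base) in (("G", "T"), ("T", "G")):
        return "wobble"
    return "mismatch"


def _luts(scheme: WobbleScoreScheme) -> np.ndarray:
    """5x5 doubled-score table indexed by (sRNA base, duplex-comparison base).

    The comparison base is the character of the reverse-complemented
    transcript, so a Watson-Crick duplex pair appears as equal characters and
    the wobbles (sRNA G : target U) and (sRNA U : target G) appear as (G, A)
    and (T, C).
    """
    m2, x2, _, w2, _ = scheme.x2
    lut = np.full((5, 5), x2, dtype=np.int32)
    for b in "ACGT":
        lut[_BASES.index(b), _BASES.index(b)] = m2
    lut[_BASES.index("G"), _BASES.index("A")] = w2
    lut[_BASES.index("T"), _BASES.index("C")] = w2
    return lut


def _scan_strand(
    srna: str, comp_chars: str, scheme: WobbleScoreScheme
) -> list[tuple[int, int, int, str]]:
    """Scan one duplex orientation.

    ``comp_chars`` is the reverse complement of the targeted transcript.
    Returns overlap-resolved local optima as (score_x2, start, end,
    pairing_string) in ``comp_chars`` coordinates.
    """
    m = len(srna)
    n = len(comp_chars)
    if n == 0 or m == 0:
        return []
    lut = _luts(scheme)
    g2 = scheme.x2[2]
    cut2 = scheme.x2[4]
    q = np.frombuffer(srna.encode().translate(_ENC), dtype=np.uint8)
    t = np.frombuffer(comp_chars.encode().translate(_ENC), dtype=np.uint8)
    H = np.zeros((m, n), dtype=np.int32)
    jarr = np.arange(n)
    gj = (-g2) * jarr
    prev = np.zeros(n, dtype=np.int32)
    D = np.zeros(n, dtype=np.int32)
    U = np.zeros(n, dtype=np.int32)
    for i in range(m):
        sc = lut[q[i], t]
        D[1:] = prev[:-1]
        D[0] = 0
        U[:] = prev
        T = np.maximum(0, np.maximum(D + sc, U + g2))
        H[i] = np.maximum.accumulate(T + gj) - gj
        prev = H[i]
    thresh = cut2 + 1 if scheme.strict_cutoff else cut2
    hi, hj = np.nonzero(H >= thresh)
    if len(hi) == 0:
        return []
    keep = np.ones(len(hi), dtype=bool)
    ok = (hi + 1 < m) & (hj + 1 < n)
    keep[ok] = H[hi[ok] + 1, hj[ok] + 1] < H[hi[ok], hj[ok]]
    cands = []
    for i, j in zip(hi[keep], hj[keep]):
        i = int(i)
        j = int(j)
        score = int(H[i, j])
        cols: list[str] = []
        ii, jj = i, j
        while True:
            sc = int(lut[q[ii], t[jj]])
            prevd = int(H[ii - 1, jj - 1]) if (ii >= 1 and jj >= 1) else 0
            if int(H[ii, jj]) == prevd + sc:
                if sc == scheme.x2[0]:
                    cols.append(MATCH)
                elif sc == scheme.x2[3]:
                    cols.append(WOBBLE)
                else:
                    cols.append(MISMATCH)
                if ii >= 1 and jj >= 1 and prevd > 0:
                    ii, jj = ii - 1, jj - 1
                    continue
                break
            if ii >= 1 and int(H[ii, jj]) == int(H[ii - 1, jj]) + g2:
                cols.append(GAP)  # gap in the target strand
                ii -= 1
                continue
            if jj >= 1 and int(H[ii, jj]) == int(H[ii, jj - 1]) + g2:
                cols.append(GAP)  # gap in the sRNA strand
                jj -= 1
                continue
            raise AssertionError("traceback failed")
        cols.reverse()
        cands.append((score, jj, j + 1, "".join(cols)))
    # maximal-scoring hit per overlapping cluster; ties: fewer gaps, leftmost
    cands.sort(key=lambda c: (-c[0], c[3].count(GAP), c[1], c[2]))
    taken = np.zeros(n, dtype=bool)
    out = []
    for score, start, end, pairing in cands:
        if taken[start:end].any():
            continue
        taken[start:end] = True
        out.append((score, start, end, pairing))
    return out


def scan_targets(
    srna: str | tuple[str, str],
    target: LocusSequence,
    scheme: WobbleScoreScheme = WobbleScoreScheme(),
    min_len: int = 18,
    max_len: int = 27,
) -> list[TargetHit]:
    """All non-overlapping local duplex optima at or above the cutoff, both strands.

    ``srna`` is the small RNA sequence 5'->3' (optionally an (id, sequence)
    pair). A perfect complement of length L scores exactly L; no hit can
    exceed the sRNA length.
    """
    if isinstance(srna, tuple):
        srna_id, seq = srna
    else:
        srna_id, seq = "sRNA", srna
    seq = seq.upper().replace("U", "T")
    if not (min_len <= len(seq) <= max_len):
        raise ValueError(f"sRNA length {len(seq)} outside [{min_len}, {max_len}]")
    n = target.length
    hits: list[TargetHit] = []
    # + strand transcript: compare against revcomp(target); map coords back
    for score, start, end, pairing in _scan_strand(seq, revcomp(target.residues), scheme):
        iv = Interval(target.id, n - end, n - start, "+")
        hits.append(TargetHit(srna_id, iv, score, pairing))
    # - strand transcript: its reverse complement is the forward target
    for score, start, end, pairing in _scan_strand(seq, target.residues, scheme):
        iv = Interval(target.id, start, end, "-")
        hits.append(TargetHit(srna_id, iv, score, pairing))
    hits.sort(key=lambda h: (h.target.start, h.target.strand, -h.score_x2))
    return hits


def merge_hit_regions(hits: Sequence[TargetHit]) -> list[tuple[Interval, TargetHit]]:
    """Merge overlapping same-sequence, same-strand hits (possibly from
    different sRNAs) into target regions; report each region with its best hit."""
    ordered = sorted(hits, key=lambda h: (h.target.seq_id, h.target.strand, h.target.start))
    regions: list[tuple[Interval, TargetHit]] = []
    for h in ordered:
        if regions:
            iv, best = regions[-1]
            if (
                iv.seq_id == h.target.seq_id
                and iv.strand == h.target.strand
                and h.target.start < iv.end
            ):
                merged = Interval(iv.seq_id, iv.start, max(iv.end, h.target.end), iv.strand)
                better = h if h.score_x2 > best.score_x2 else best
                regions[-1] = (merged, better)
                continue
        regions.append((h.target, h))
    return regions
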