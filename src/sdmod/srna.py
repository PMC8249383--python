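"""Small-RNA read filtering, mapping and per-precursor quantification.

Mapping is an exact / near-exact full scan of the supplied locus sequences
(both strands, all equally good placements reported), which is appropriate at
the scale of S-locus haplotypes and keeps a naive-scan oracle cheap. Reads
containing N are unmappable at 0 mismatches; in 1-mismatch mode an N column
counts as a mismatch (N never matches anything).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .io import Interval, LocusSequence, SmallReadSet, revcomp

READ_MIN_LEN = 18
READ_MAX_LEN = 27


@dataclass(frozen=True)
class MappedRead:
    read: str
    count: int
    seq_id: str
    position: int  # 0-based start on the + strand of the reference
    strand: str
    n_placements: int

    @property
    def end(self) -> int:
        return self.position + len(self.read)


@dataclass(frozen=True)
class PrecursorExpression:
    precursor: Interval
    total_count: float
    size_histogram: Mapping[int, float]
    coverage: np.ndarray = field(repr=False, compare=False)


def filter_reads(
    reads: SmallReadSet,
    adapter: str | None = None,
    min_len: int = READ_MIN_LEN,
    max_len: int = READ_MAX_LEN,
    min_adapter_overlap: int = 8,
) -> SmallReadSet:
    """Clip 3' adapters, enforce the 18-27 nt length window, collapse duplicates.

    Adapter clipping removes the read suffix from the first position where a
    prefix of ``adapter`` of length >= ``min_adapter_overlap`` matches exactly
    through the read end.
    """
    counts: Counter[str] = Counter()
    for seq, count in reads.reads:
        if adapter:
            for i in range(len(seq) - min_adapter_overlap + 1):
                tail = seq[i:]
                if adapter.startswith(tail) or tail.startswith(adapter):
                    seq = seq[:i]
                    break
        if min_len <= len(seq) <= max_len:
            counts[seq] += count
    collapsed = tuple(sorted(counts.items()))
    return SmallReadSet(tuple((s, c) for s, c in collapsed), min_len, max_len)


def _scan_exact(ref: str, query: str) -> list[int]:
    out = []
    start = ref.find(query)
    while start != -1:
        out.append(start)
        start = ref.find(query, start + 1)
    return out


def _scan_one_mismatch(ref_arr: np.ndarray, ref_n: np.ndarray, query: str) -> list[int]:
    """Positions with <= 1 mismatch; N on either side counts as a mismatch."""
    L = len(query)
    if L > len(ref_arr):
        return []
    q = np.frombuffer(query.encode(), dtype=np.uint8)
    qn = q == ord("N")
    windows = np.lib.stride_tricks.sliding_window_view(ref_arr, L)
    nwin = np.lib.stride_tricks.sliding_window_view(ref_n, L)
    mism = (windows != q) | nwin | qn
    return list(np.nonzero(mism.sum(axis=1) <= 1)[0])


def map_reads(
    reads: SmallReadSet,
    refs: Sequence[LocusSequence],
    max_mismatches: int = 0,
) -> list[MappedRead]:
    """Report every placement of every read on either strand of every reference.

    ``n_placements`` counts equally good placements across all references and
    strands; output order is deterministic (read, seq_id, position, strand).
    """
    if max_mismatches not in (0, 1):
        raise ValueError("max_mismatches must be 0 or 1")
    prepared = []
    for ref in refs:
        arr = np.frombuffer(ref.residues.encode(), dtype=np.uint8)
        prepared.append((ref, arr, arr == ord("N")))
    out: list[MappedRead] = []
    for seq, count in reads.reads:
        placements: list[tuple[str, int, str]] = []
        for ref, arr, narr in prepared:
            for strand, query in (("+", seq), ("-", revcomp(seq))):
                if max_mismatches == 0:
                    hits = [] if "N" in query else _scan_exact(ref.residues, query)
                    # exact string equality would let N==N slip through; forbid
                    if "N" not in query:
                        hits = [h for h in hits if "N" not in ref.residues[h : h + len(query)]]
                else:
                    hits = _scan_one_mismatch(arr, narr, query)
                placements.extend((ref.id, int(h), strand) for h in hits)
        n = len(placements)
        for sid, pos, strand in placements:
            out.append(MappedRead(seq, count, sid, pos, strand, n))
    out.sort(key=lambda m: (m.read, m.seq_id, m.position, m.strand))
    return out


def quantify(
    mapped: Sequence[MappedRead],
    precursors: Sequence[Interval],
    weight_multimappers: bool = True,
    unique_only: bool = False,
) -> list[PrecursorExpression]:
    """Per-precursor expression: copies of reads overlapping by >= 1 nt.

    Multi-placement reads contribute ``count / n_placements`` per placement by
    default; ``unique_only`` drops them instead. ``coverage`` is the weighted
    per-position read depth inside the precursor.
    """
    out = []
    for prec in precursors:
        total = 0.0
        hist: dict[int, float] = {size: 0.0 for size in range(READ_MIN_LEN, READ_MAX_LEN + 1)}
        cov = np.zeros(len(prec), dtype=float)
        for m in mapped:
            if m.seq_id != prec.seq_id:
                continue
            if m.position >= prec.end or m.end <= prec.start:
                continue
            if unique_only and m.n_placements > 1:
                continue
            w = m.count / m.n_placements if weight_multimappers else float(m.count)
            total += w
            hist[len(m.read)] = hist.get(len(m.read), 0.0) + w
            lo = max(m.position, prec.start) - prec.start
            hi = min(m.end, prec.end) - prec.start
            cov[lo:hi] += w
        out.append(PrecursorExpression(prec, total, hist, cov))
    return out
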