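"""Sequence/interval data model and readers/writers for the formats the pipeline touches.

Conventions used throughout the package:

* internal coordinates are 0-based half-open; GFF3 output converts to the
  standard 1-based inclusive convention;
* RNA input is normalized to the DNA alphabet at ingest (U -> T), so the
  wobble logic downstream is defined on the T-normalized alphabet;
* ``N`` is a valid residue but never counts as a match, pair or wobble
  anywhere downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO


class FormatError(ValueError):
    """A file does not conform to its declared format."""


class BoundsError(ValueError):
    """An interval lies outside the sequence it refers to."""


_VALID = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
#: Watson-Crick pairs on the T-normalized alphabet. G:T is *not* here; wobble
#: pairing is admitted only by the hairpin filter and the target scorer.
WC_PAIRS = frozenset({("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")})


def normalize_residues(raw: str) -> str:
    """Uppercase and convert U to T. Raises ``ValueError`` on non-IUPAC-N residues."""
    s = raw.upper().replace("U", "T")
    bad = set(s) - _VALID
    if bad:
        raise ValueError(f"invalid nucleotide character(s): {sorted(bad)}")
    return s


def revcomp(s: str) -> str:
    """Reverse complement on the T-normalized alphabet (N maps to N)."""
    return s.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class LocusSequence:
    """A named nucleotide sequence: the S-haplotype unit of analysis."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("LocusSequence id must be non-empty")
        object.__setattr__(self, "residues", normalize_residues(self.residues))

    @property
    def length(self) -> int:
        return len(self.residues)

    def __len__(self) -> int:
        return len(self.residues)

    def subseq(self, start: int, end: int) -> str:
        if not (0 <= start < end <= len(self.residues)):
            raise BoundsError(f"[{start}, {end}) outside {self.id} (length {self.length})")
        return self.residues[start:end]

    def reverse_complement(self, new_id: str | None = None) -> "LocusSequence":
        return LocusSequence(new_id or self.id, revcomp(self.residues))


@dataclass(frozen=True, order=True)
class Interval:
    """0-based half-open interval on a named sequence."""

    seq_id: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return self.seq_id == other.seq_id and self.start < other.end and other.start < self.end

    def contains(self, other: "Interval") -> bool:
        return self.seq_id == other.seq_id and self.start <= other.start and other.end <= self.end


@dataclass(frozen=True)
class SmallReadSet:
    """Collapsed small-RNA reads as (sequence, copy count) pairs."""

    reads: tuple[tuple[str, int], ...]
    min_len: int
    max_len: int

    def __post_init__(self) -> None:
        for seq, count in self.reads:
            if count < 1:
                raise ValueError(f"copy count must be >= 1, got {count} for {seq}")
            if not (self.min_len <= len(seq) <= self.max_len):
                raise ValueError(
                    f"read of length {len(seq)} outside [{self.min_len}, {self.max_len}]"
                )

    @property
    def total_copies(self) -> int:
        return sum(c for _, c in self.reads)

    def __len__(self) -> int:
        return len(self.reads)


# ---------------------------------------------------------------------------
# FASTA / FASTQ


def _first_bad_line(path: str | Path) -> int | None:
    """1-based line number of the first sequence line with a non-nucleotide char."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith(">"):
                continue
            if set(stripped.upper().replace("U", "T")) - _VALID:
                return lineno
    return None


def read_fasta(path: str | Path) -> list[LocusSequence]:
    """Read a nucleotide FASTA file into a list of :class:`LocusSequence`.

    Residues are normalized (U->T, uppercased); record order is preserved.
    Malformed headers or non-IUPAC residues raise :class:`FormatError`
    naming the offending line.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.strip():
                if not line.startswith(">"):
                    raise FormatError(f"{path}:{lineno}: expected FASTA header '>', got {line.strip()[:30]!r}")
                break
    records: list[LocusSequence] = []
    with open(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if not rec.id:
                raise FormatError(f"{path}: FASTA record with empty header")
            try:
                records.append(LocusSequence(rec.id, str(rec.seq)))
            except ValueError as exc:
                lineno = _first_bad_line(path)
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return records


def write_fasta(records: Iterable[LocusSequence], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


def load_reads(path: str | Path, fmt: str | None = None) -> SmallReadSet:
    """Load raw small-RNA reads from FASTA or FASTQ (qualities parsed but unused).

    Returns an uncollapsed read set (each record count 1); use
    :func:`sdmod.srna.filter_reads` for adapter clipping, the 18-27 nt length
    filter and copy-count collapsing.
    """
    path = Path(path)
    if fmt is None:
        with open(path) as fh:
            first = fh.read(1)
        fmt = "fastq" if first == "@" else "fasta"
    reads: list[tuple[str, int]] = []
    max_len = 1
    with open(path) as fh:
        for rec in SeqIO.parse(fh, fmt):
            seq = normalize_residues(str(rec.seq))
            if seq:
                reads.append((seq, 1))
                max_len = max(max_len, len(seq))
    return SmallReadSet(tuple(reads), min_len=1, max_len=max_len)


# ---------------------------------------------------------------------------
# GFF3

_GFF_SOURCE = "sdmod"


def _fmt_score(score: float | int | None) -> str:
    if score is None:
        return "."
    if float(score) == int(score):
        return str(int(score))
    return f"{float(score):g}"


def write_gff3(
    features: Iterable[tuple[Interval, str, float | None, Mapping[str, str]]],
    path: str | Path,
    seq_lengths: Mapping[str, int] | None = None,
) -> None:
    """Write features as GFF3 (1-based inclusive), ordered by (seq_id, start).

    ``features`` are (interval, type, score, attributes) tuples. Intervals
    exceeding a declared sequence length raise :class:`BoundsError`.
    """
    feats = sorted(features, key=lambda f: (f[0].seq_id, f[0].start, f[0].end, f[1]))
    if seq_lengths is not None:
        for iv, ftype, _, _ in feats:
            if iv.seq_id in seq_lengths and iv.end > seq_lengths[iv.seq_id]:
                raise BoundsError(
                    f"{ftype} [{iv.start}, {iv.end}) exceeds length {seq_lengths[iv.seq_id]} of {iv.seq_id}"
                )
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        if seq_lengths:
            for sid in sorted(seq_lengths):
                fh.write(f"##sequence-region {sid} 1 {seq_lengths[sid]}\n")
        for iv, ftype, score, attrs in feats:
            attr_str = ";".join(f"{k}={v}" for k, v in attrs.items()) or "."
            fh.write(
                "\t".join(
                    [
                        iv.seq_id,
                        _GFF_SOURCE,
                        ftype,
                        str(iv.start + 1),
                        str(iv.end),
                        _fmt_score(score),
                        iv.strand,
                        ".",
                        attr_str,
                    ]
                )
                + "\n"
            )


def read_gff3(path: str | Path) -> list[tuple[Interval, str, float | None, dict[str, str]]]:
    """Re-parse a GFF3 file into internal 0-based half-open intervals."""
    out: list[tuple[Interval, str, float | None, dict[str, str]]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 tab-separated columns")
            seq_id, _, ftype, start, end, score, strand, _, attr_str = cols
            try:
                iv = Interval(seq_id, int(start) - 1, int(end), strand if strand in "+-" else "+")
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            sc = None if score == "." else float(score)
            attrs = {}
            if attr_str != ".":
                for item in attr_str.split(";"):
                    if item:
                        k, _, v = item.partition("=")
                        attrs[k] = v
            out.append((iv, ftype, sc, attrs))
    return out


# ---------------------------------------------------------------------------
# Depth tables (samtools-depth style TSV: seq_id, 1-based position, depth)


def read_depth_table(
    path: str | Path, seq_lengths: Mapping[str, int] | None = None
) -> dict[str, np.ndarray]:
    """Read a per-base depth TSV into 0-based depth arrays keyed by seq_id.

    Positions absent from the file have depth 0. If ``seq_lengths`` is given,
    arrays are padded to the declared length (and positions beyond it raise
    :class:`BoundsError`); otherwise the array ends at the last seen position.
    """
    depths: dict[str, dict[int, int]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 3:
                raise FormatError(f"{path}:{lineno}: expected 3 tab-separated columns")
            sid, pos_s, depth_s = cols
            try:
                pos = int(pos_s)
                depth = int(depth_s)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer position or depth") from exc
            if pos < 1:
                raise FormatError(f"{path}:{lineno}: positions are 1-based, got {pos}")
            if depth < 0:
                raise FormatError(f"{path}:{lineno}: negative depth {depth}")
            depths.setdefault(sid, {})[pos - 1] = depth
    out: dict[str, np.ndarray] = {}
    ids = set(depths)
    if seq_lengths is not None:
        ids |= set(seq_lengths)
    for sid in sorted(ids):
        seen = depths.get(sid, {})
        if seq_lengths is not None and sid in seq_lengths:
            length = seq_lengths[sid]
            if seen and max(seen) >= length:
                raise BoundsError(f"{path}: position {max(seen) + 1} beyond length {length} of {sid}")
        else:
            length = (max(seen) + 1) if seen else 0
        arr = np.zeros(length, dtype=np.int64)
        for p, d in seen.items():
            arr[p] = d
        out[sid] = arr
    return out


def write_depth_table(depths: Mapping[str, np.ndarray], path: str | Path) -> None:
    """Write per-base depths as a samtools-depth style TSV (zero rows omitted)."""
    with open(path, "w") as fh:
        for sid in sorted(depths):
            arr = depths[sid]
            for pos in np.nonzero(arr)[0]:
                fh.write(f"{sid}\t{pos + 1}\t{int(arr[pos])}\n")
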