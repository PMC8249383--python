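"""SCR/SRK annotation helpers and the coverage-based presence classifier.

Three independent operations:

* :func:`call_frameshifts` aligns a candidate coding sequence to an intact
  reference CDS and classifies it as intact or a frameshift pseudogene from
  the frame-disrupting (length % 3 != 0) indels it carries;
* :func:`scan_cysteine_pattern` searches all six reading frames for the
  8-cysteine signature of the pollen-coat SCR protein;
* :func:`classify_coverage` turns a per-base read-depth profile into an
  S-haplotype presence call from breadth and evenness of coverage.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from Bio.Align import PairwiseAligner
from Bio.Seq import Seq

from .io import Interval, LocusSequence, revcomp


@dataclass(frozen=True)
class Indel:
    """A gap run in the candidate/reference alignment.

    ``position`` is the reference CDS coordinate of the gap; ``kind`` is
    'deletion' (bases missing from the candidate) or 'insertion'.
    """

    position: int
    length: int
    kind: str

    @property
    def frame_disrupting(self) -> bool:
        return self.length % 3 != 0


@dataclass(frozen=True)
class GeneCall:
    gene: str
    interval: Interval
    status: str  # intact | frameshift_pseudogene | not_found
    indels: tuple[Indel, ...]


@dataclass(frozen=True)
class CysteinePattern:
    """Expected count and inter-cysteine spacing windows (amino acids, inclusive)."""

    n_cys: int = 8
    spacing_windows: tuple[tuple[int, int], ...] = tuple([(2, 40)] * 7)

    def __post_init__(self) -> None:
        if len(self.spacing_windows) != self.n_cys - 1:
            raise ValueError("need n_cys - 1 spacing windows")
        for lo, hi in self.spacing_windows:
            if not (0 < lo <= hi):
                raise ValueError(f"invalid spacing window ({lo}, {hi})")


@dataclass(frozen=True)
class CoverageCall:
    seq_id: str
    breadth: float
    mean_depth: float
    evenness: float
    present: bool


def _cds_aligner() -> PairwiseAligner:
    # spec'd costs: match +1, mismatch -1, gap open -5, extend -1; Biopython
    # charges open+extend on the first gap residue, hence -6
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -6
    aligner.extend_gap_score = -1
    return aligner


def call_frameshifts(
    candidate_cds: LocusSequence, reference_cds: LocusSequence, gene: str = "SCR"
) -> GeneCall:
    """Classify a candidate CDS against an intact reference by its indels.

    Indels are interior gap runs of the best global pairwise alignment;
    terminal overhangs (length differences at the alignment ends) are not
    treated as indel evidence. The call is ``frameshift_pseudogene`` iff any
    indel length is not a multiple of three.
    """
    if candidate_cds.length == 0 or reference_cds.length == 0:
        raise ValueError("empty sequence")
    if reference_cds.length % 3 != 0:
        raise ValueError("reference CDS length must be divisible by 3")
    aln = _cds_aligner().align(reference_cds.residues, candidate_cds.residues)[0]
    ref_blocks, cand_blocks = aln.aligned
    indels: list[Indel] = []
    for k in range(1, len(ref_blocks)):
        d_ref = int(ref_blocks[k][0] - ref_blocks[k - 1][1])
        d_cand = int(cand_blocks[k][0] - cand_blocks[k - 1][1])
        pos = int(ref_blocks[k - 1][1])
        if d_ref > 0:
            indels.append(Indel(pos, d_ref, "deletion"))
        if d_cand > 0:
            indels.append(Indel(pos, d_cand, "insertion"))
    status = (
        "frameshift_pseudogene" if any(i.frame_disrupting for i in indels) else "intact"
    )
    return GeneCall(
        gene,
        Interval(candidate_cds.id, 0, candidate_cds.length),
        status,
        tuple(sorted(indels, key=lambda i: (i.position, i.kind))),
    )


def _frame_hits(
    protein: str, frame_nt_offset: int, pattern: CysteinePattern
) -> list[tuple[int, int]]:
    """Nucleotide [start, end) windows (frame-local coords) of matching motifs."""
    cys = [i for i, aa in enumerate(protein) if aa == "C"]
    hits = []
    k = pattern.n_cys
    for w in range(len(cys) - k + 1):
        window = cys[w : w + k]
        gaps = [window[t + 1] - window[t] for t in range(k - 1)]
        if all(lo <= gap <= hi for gap, (lo, hi) in zip(gaps, pattern.spacing_windows)):
            if "*" in protein[window[0] : window[-1] + 1]:
                continue
            hits.append((frame_nt_offset + 3 * window[0], frame_nt_offset + 3 * (window[-1] + 1)))
    return hits


def scan_cysteine_pattern(
    seq: LocusSequence, pattern: CysteinePattern = CysteinePattern()
) -> list[Interval]:
    """SCR candidate windows: 8 cysteines at admissible spacings, any of the
    six reading frames, no stop codon inside the motif."""
    n = seq.length
    out: list[Interval] = []
    for strand, residues in (("+", seq.residues), ("-", revcomp(seq.residues))):
        for frame in range(3):
            sub = residues[frame:]
            sub = sub[: len(sub) - len(sub) % 3]
            if not sub:
                continue
            protein = str(Seq(sub).translate())
            for start, end in _frame_hits(protein, frame, pattern):
                if strand == "+":
                    out.append(Interval(seq.id, start, end, "+"))
                else:
                    out.append(Interval(seq.id, n - end, n - start, "-"))
    out.sort(key=lambda iv: (iv.start, iv.end, iv.strand))
    return out


def classify_coverage(
    depths: np.ndarray | Sequence[int],
    min_depth: int = 1,
    breadth_threshold: float = 0.9,
    seq_id: str = "",
) -> CoverageCall:
    """Presence call from a per-base depth profile.

    breadth   = fraction of positions with depth >= min_depth
    evenness  = fraction of positions within [0.25x, 4x] of the median depth
    present   = breadth >= breadth_threshold
    """
    arr = np.asarray(depths, dtype=float)
    if arr.ndim != 1 or arr.size < 1:
        raise ValueError("depth array must be 1-D and non-empty")
    breadth = float((arr >= min_depth).mean())
    med = float(np.median(arr))
    evenness = float(((arr >= 0.25 * med) & (arr <= 4 * med)).mean())
    return CoverageCall(seq_id, breadth, float(arr.mean()), evenness, breadth >= breadth_threshold)
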