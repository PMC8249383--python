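"""Hairpin-precursor evaluation of inverted repeats.

An inverted repeat is promoted to a candidate sRNA precursor when its arm
alignment looks like a miRNA-style hairpin: terminal loop shorter than 40 nt,
more than 20 paired stem columns, at most 4 mismatched columns and at most 2
asymmetric bulges. Pairing here admits the G:U wobble (G:T on the
T-normalized alphabet) because the criteria describe the folded RNA, whereas
the inverted-repeat *search* scores Watson-Crick only. The full screen
requires sRNA expression over the precursor first, then the structural rules.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .inverted_repeats import InvertedRepeat
from .io import WC_PAIRS
from .srna import PrecursorExpression

_PAIRED = WC_PAIRS | {("G", "T"), ("T", "G")}


class ConsistencyError(ValueError):
    """Expression records do not line up with the inverted repeats screened."""


@dataclass(frozen=True)
class HairpinCriteria:
    """Structural filter thresholds. Loop and stem bounds are strict
    (loop must be < ``max_terminal_loop``; paired stem must be > ``min_paired_stem``)."""

    max_terminal_loop: int = 40
    min_paired_stem: int = 20
    max_mismatches: int = 4
    max_asym_bulges: int = 2

    def __post_init__(self) -> None:
        if min(self.max_terminal_loop, self.min_paired_stem) <= 0:
            raise ValueError("loop/stem thresholds must be positive")
        if min(self.max_mismatches, self.max_asym_bulges) < 0:
            raise ValueError("mismatch/bulge limits must be >= 0")


@dataclass(frozen=True)
class HairpinCandidate:
    source: InvertedRepeat
    loop_len: int
    paired_len: int
    mismatch_count: int
    asym_bulge_count: int
    passes: bool
    expressed: bool = False

    @property
    def retained(self) -> bool:
        return self.passes and self.expressed


def _is_paired(left: str, right: str) -> bool:
    # N never pairs; '-' columns are gaps, not pairs
    return (left, right) in _PAIRED


def evaluate_hairpin(ir: InvertedRepeat, criteria: HairpinCriteria = HairpinCriteria()) -> HairpinCandidate:
    """Compute hairpin metrics from the arm alignment and apply the filter rules.

    * ``paired_len`` counts columns forming A:T, G:C or G:T pairs (summed over
      all bulge-separated stem segments, not the longest helix);
    * ``mismatch_count`` counts columns whose two bases do not pair;
    * ``asym_bulge_count`` counts maximal runs of consecutive gap columns,
      each run one bulge regardless of length.
    """
    if not ir.columns:
        raise ValueError("inverted repeat has no arm alignment")
    paired = mismatches = bulges = 0
    in_gap_run = False
    for left, right in ir.columns:
        if left == "-" or right == "-":
            if not in_gap_run:
                bulges += 1
                in_gap_run = True
            continue
        in_gap_run = False
        if _is_paired(left, right):
            paired += 1
        else:
            mismatches += 1
    loop_len = ir.loop_len
    passes = (
        loop_len < criteria.max_terminal_loop
        and paired > criteria.min_paired_stem
        and mismatches <= criteria.max_mismatches
        and bulges <= criteria.max_asym_bulges
    )
    return HairpinCandidate(ir, loop_len, paired, mismatches, bulges, passes)


def screen_candidates(
    irs: Sequence[InvertedRepeat],
    criteria: HairpinCriteria,
    expression: Sequence[PrecursorExpression],
    min_expression: float = 5.0,
    size_classes: tuple[int, int] = (21, 24),
) -> list[HairpinCandidate]:
    """Two-stage screen: sRNA expression first, then hairpin structure.

    ``expression`` must carry one record per inverted repeat, quantified over
    the same precursor interval (arm start to arm end); a mismatch raises
    :class:`ConsistencyError`. A precursor is *expressed* when its summed
    copies in the 21-24 nt size classes reach ``min_expression``; it is
    *retained* when expressed and structurally passing.
    """
    if len(expression) != len(irs):
        raise ConsistencyError(
            f"{len(expression)} expression records for {len(irs)} inverted repeats"
        )
    out: list[HairpinCandidate] = []
    lo, hi = size_classes
    for ir, expr in zip(irs, expression):
        span_start, span_end = ir.left_arm.start, ir.right_arm.end
        prec = expr.precursor
        if prec.seq_id != ir.left_arm.seq_id or (prec.start, prec.end) != (span_start, span_end):
            raise ConsistencyError(
                f"expression interval {prec.seq_id}:[{prec.start},{prec.end}) does not match "
                f"inverted repeat {ir.left_arm.seq_id}:[{span_start},{span_end})"
            )
        expressed = sum(expr.size_histogram.get(size, 0.0) for size in range(lo, hi + 1)) >= min_expression
        cand = evaluate_hairpin(ir, criteria)
        out.append(HairpinCandidate(
            cand.source, cand.loop_len, cand.paired_len, cand.mismatch_count,
            cand.asym_bulge_count, cand.passes, expressed=expressed,
        ))
    return out
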