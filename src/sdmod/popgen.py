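"""Nucleotide diversity (pi) and Watterson's theta from a coding alignment.

Missing data are handled by complete deletion: any column containing a gap
or N in any sequence is excluded, giving ``L_used``. ``S`` counts retained
columns with two or more distinct bases (multi-allelic columns count once);
pi averages pairwise per-site differences over all sequence pairs; Watterson's
estimator is ``S / (a_n * L_used)`` with ``a_n`` the (n-1)-th harmonic number.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import SeqIO

_ENC = bytes.maketrans(b"ACGTN-", bytes([0, 1, 2, 3, 4, 5]))


class UndefinedEstimateError(ValueError):
    """No usable columns remain after missing-data handling."""


@dataclass(frozen=True)
class CodingAlignment:
    """n aligned nucleotide strings of equal length (gaps '-', ambiguity N)."""

    sequences: tuple[str, ...]
    ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(self.sequences) < 2:
            raise ValueError("need at least 2 sequences")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise ValueError(f"rows have unequal lengths: {sorted(lengths)}")
        norm = tuple(s.upper().replace("U", "T") for s in self.sequences)
        for s in norm:
            bad = set(s) - set("ACGTN-")
            if bad:
                raise ValueError(f"invalid alignment characters: {sorted(bad)}")
        object.__setattr__(self, "sequences", norm)
        if not self.ids:
            object.__setattr__(self, "ids", tuple(f"seq{i}" for i in range(len(norm))))

    @property
    def n(self) -> int:
        return len(self.sequences)

    @property
    def L_total(self) -> int:
        return len(self.sequences[0])

    @classmethod
    def from_fasta(cls, path: str | Path) -> "CodingAlignment":
        ids, seqs = [], []
        with open(path) as fh:
            for rec in SeqIO.parse(fh, "fasta"):
                ids.append(rec.id)
                seqs.append(str(rec.seq))
        return cls(tuple(seqs), tuple(ids))


@dataclass(frozen=True)
class DiversityEstimates:
    pi: float
    theta_w: float
    S: int
    n: int
    L_used: int
    a_n: float


def watterson_a(n: int) -> float:
    """Harmonic number sum_{i=1}^{n-1} 1/i."""
    if n < 2:
        raise ValueError("n must be >= 2")
    return float(sum(1.0 / i for i in range(1, n)))


def diversity(aln: CodingAlignment) -> DiversityEstimates:
    """Per-site pi and Watterson's theta under complete deletion of gap/N columns."""
    arr = np.vstack(
        [np.frombuffer(s.encode().translate(_ENC), dtype=np.uint8) for s in aln.sequences]
    )
    usable = (arr <= 3).all(axis=0)
    L_used = int(usable.sum())
    if L_used == 0:
        raise UndefinedEstimateError("no usable columns after complete deletion")
    sub = arr[:, usable]
    n = aln.n
    S = int((sub != sub[0]).any(axis=0).sum())
    total_diff = 0
    for i in range(n):
        for j in range(i + 1, n):
            total_diff += int((sub[i] != sub[j]).sum())
    n_pairs = n * (n - 1) // 2
    pi = total_diff / (n_pairs * L_used)
    a_n = watterson_a(n)
    theta_w = S / (a_n * L_used)
    return DiversityEstimates(pi, theta_w, S, n, L_used, a_n)
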