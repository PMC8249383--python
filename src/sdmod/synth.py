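"""Seeded generator of synthetic S-locus study inputs.

The generator emulates the structure every pipeline stage assumes, at the
scale the study reports: two homeologous S-haplotypes with the gene order
U-box - mirS3 - SCR - SRK - ARK3; a planted hairpin precursor inside mirS3
of the B-like (C. orientalis-derived) haplotype; small-RNA reads expressed
from that precursor; a planted target site of designed wobble-scored
affinity on the A-like (C. grandiflora-derived) haplotype near degenerate
SCR fragments; a frameshift deletion (1 bp or 31 bp) in the B SCR; infinite-
sites population samples of an SRK-sized coding region at a stated theta;
and read-depth profiles for present/absent haplotypes.

Every operation draws from its own pseudo-random stream derived from
(seed, operation tag), so outputs are byte-identical for a fixed seed and
adding an operation never perturbs another's stream. Background sequence is
i.i.d. over the configured base composition -- no repeat structure beyond
the planted features, which is sufficient for filter testing but declaredly
unrealistic.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from math import comb
from typing import Mapping, Sequence

import numpy as np

from .io import Interval, LocusSequence, SmallReadSet, revcomp
from .popgen import CodingAlignment, watterson_a

A_ID = "S_locus_A"
B_ID = "S_locus_B"

_GUARD = "AAAAAA"  # A:A never pairs/wobbles, so local alignment stops here
#: right-arm base that neither Watson-Crick- nor wobble-pairs the left base
_NONPAIRING = {"A": "G", "C": "T", "G": "A", "T": "C"}
_MISMATCH_FRACS = (0.30, 0.55, 0.72, 0.88)
_BULGE_FRACS = (0.42, 0.65)
_READ_LEN_DIST = {21: 0.15, 22: 0.15, 23: 0.20, 24: 0.50}
_NONSTOP_NONCYS_CODONS = tuple(
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA", "TGT", "TGC")
)
_SCR_CYS_AA = (20, 25, 31, 38, 46, 55, 65, 76)  # spacings 5..11, inside (2, 40)
_SCR_CODONS = 110


class SyntheticConfigError(ValueError):
    """The requested synthetic scenario is internally infeasible."""


@dataclass(frozen=True)
class HairpinSpec:
    arm_len: int = 60
    loop_len: int = 10
    n_mismatches: int = 2
    n_bulges: int = 1

    def __post_init__(self) -> None:
        if self.arm_len < 25:
            raise SyntheticConfigError("arm_len must be >= 25")
        if self.n_mismatches > len(_MISMATCH_FRACS) or self.n_bulges > len(_BULGE_FRACS):
            raise SyntheticConfigError("too many mismatches/bulges requested")

    @property
    def expected_ir_score(self) -> int:
        """einverted-style score of the designed arm alignment (match +4,
        mismatch -4, one single-base bulge -8)."""
        return 4 * self.arm_len - 8 * self.n_mismatches - 8 * self.n_bulges


@dataclass(frozen=True)
class SyntheticConfig:
    seed: int = 1
    locus_len: int = 30000
    hairpin: HairpinSpec = field(default_factory=HairpinSpec)
    scr_deletion_len: int = 1  # 0, 1 or 31
    srna_len: int = 24
    target_affinity: float = 19.0
    target_wobbles: int = 2
    srna_depth: float = 2.0  # expected read copies per precursor arm position
    mature_enrichment: float = 25.0  # accumulation of the designated mature sRNA
    background_reads: int = 50
    theta_true: float = 0.001
    n_samples: int = 4
    pop_length: int = 25000
    base_composition: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    depth_mean: float = 20.0

    def __post_init__(self) -> None:
        if self.scr_deletion_len not in (0, 1, 31):
            raise SyntheticConfigError("scr_deletion_len must be 0, 1 or 31")
        if abs(sum(self.base_composition) - 1.0) > 1e-9:
            raise SyntheticConfigError("base_composition must sum to 1")
        if self.srna_len + 6 > self.hairpin.arm_len:
            raise SyntheticConfigError("sRNA window does not fit inside the hairpin arm")
        # affinity decomposition: score = L - 1.5*w - 2*x with x mismatches
        self.target_edits()  # raises if infeasible

    def target_edits(self) -> tuple[int, int]:
        """(wobbles, mismatches) realizing ``target_affinity`` on a gapless site."""
        if self.target_affinity > self.srna_len:
            raise SyntheticConfigError(
                f"affinity {self.target_affinity} exceeds sRNA length {self.srna_len}"
            )
        w = self.target_wobbles
        four_x = 2 * self.srna_len - 3 * w - int(round(2 * self.target_affinity))
        if four_x < 0 or four_x % 4 != 0:
            raise SyntheticConfigError(
                f"affinity {self.target_affinity} unreachable with {w} wobbles "
                f"on a {self.srna_len}-nt sRNA"
            )
        return w, four_x // 4


def _rng(seed: int, tag: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, zlib.crc32(tag.encode())]))


def _random_seq(rng: np.random.Generator, length: int, comp: Sequence[float]) -> str:
    if length <= 0:
        return ""
    return "".join(rng.choice(list("ACGT"), size=length, p=list(comp)))


@dataclass(frozen=True)
class PlantedFeature:
    name: str
    seq_id: str
    start: int
    end: int
    strand: str = "+"
    attrs: Mapping[str, object] = field(default_factory=dict)

    @property
    def interval(self) -> Interval:
        return Interval(self.seq_id, self.start, self.end, self.strand)


@dataclass(frozen=True)
class TruthTable:
    """Coordinates and expected scores of every planted feature."""

    features: tuple[PlantedFeature, ...]

    def __getitem__(self, name: str) -> PlantedFeature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)

    def gff3_rows(self):
        return [
            (f.interval, f.name, f.attrs.get("expected_score"), {"ID": f.name})
            for f in self.features
        ]


def _make_scr_reference(seed: int) -> str:
    rng = _rng(seed, "scr_ref")
    codons = list(rng.choice(_NONSTOP_NONCYS_CODONS, size=_SCR_CODONS))
    codons[0] = "ATG"
    for aa in _SCR_CYS_AA:
        codons[aa] = "TGC"
    return "".join(codons)


def _build_hairpin(cfg: SyntheticConfig) -> dict:
    """Designed precursor block with guards; metrics hold by construction."""
    hp = cfg.hairpin
    rng = _rng(cfg.seed, "hairpin")
    w, x = cfg.target_edits()
    interior = range(4, cfg.srna_len - 4)
    srna_off = 3
    while True:
        left = _random_seq(rng, hp.arm_len, cfg.base_composition)
        window = left[srna_off : srna_off + cfg.srna_len]
        eligible = [p for p in interior if window[p] in "GT"]
        if len(eligible) >= w and len(interior) - w >= x:
            break
    # right arm pairs the left arm exactly, then designed edits break pairing
    right = list(revcomp(left))
    for frac in _MISMATCH_FRACS[: hp.n_mismatches]:
        p = int(frac * hp.arm_len)  # left-arm index
        right[hp.arm_len - 1 - p] = _NONPAIRING[left[p]]
    for frac in _BULGE_FRACS[: hp.n_bulges]:
        q = int(frac * len(right))
        for base in "ACGT":
            if base != right[q - 1] and base != right[q]:
                right.insert(q, base)
                break
    # all-A loop: A:A neither pairs nor wobbles, so the local aligner can
    # never profitably extend the stem into the loop and the designed arm
    # boundaries are recovered exactly
    loop = ["A"] * hp.loop_len
    return {
        "left": left,
        "right": "".join(right),
        "loop": "".join(loop),
        "block": _GUARD + left + "".join(loop) + "".join(right) + _GUARD,
        "srna": window,
        "srna_off": srna_off,
        "wobble_positions": sorted(
            [p for p in interior if window[p] in "GT"][:w]
        ),
    }


def _build_target_site(cfg: SyntheticConfig, hairpin: dict) -> str:
    """Gapless site on the A-like + strand whose duplex score with the
    designated sRNA equals the configured affinity."""
    srna = hairpin["srna"]
    L = cfg.srna_len
    w, x = cfg.target_edits()
    site = list(revcomp(srna))
    used = set()
    for p in hairpin["wobble_positions"]:
        q = L - 1 - p
        site[q] = "T" if srna[p] == "G" else "G"
        used.add(p)
    placed = 0
    for p in range(4, L - 4):
        if placed == x:
            break
        if p in used:
            continue
        site[L - 1 - p] = srna[p]  # identical bases never pair nor wobble
        placed += 1
    if placed != x:
        raise SyntheticConfigError("could not place designed mismatches")
    return "".join(site)


def make_haplotype_pair(cfg: SyntheticConfig = SyntheticConfig()):
    """Build the A-like and B-like S-haplotypes plus the planted-feature truth table."""
    comp = cfg.base_composition
    scale = cfg.locus_len / 30000.0

    def bg(rng, nominal):
        return _random_seq(rng, max(0, int(nominal * scale)), comp)

    rng_shared = _rng(cfg.seed, "shared_genes")
    ubox = _random_seq(rng_shared, 1200, comp)
    ark3 = _random_seq(rng_shared, 1800, comp)
    scr_ref = _make_scr_reference(cfg.seed)
    hairpin = _build_hairpin(cfg)
    target_site = _build_target_site(cfg, hairpin)

    # ----- B-like haplotype -----
    rng_b = _rng(cfg.seed, "background_b")
    srk_b = _random_seq(_rng(cfg.seed, "srk_b"), 2500, comp)
    if cfg.scr_deletion_len:
        del_pos = 130 if cfg.scr_deletion_len == 1 else 125
        scr_b = scr_ref[:del_pos] + scr_ref[del_pos + cfg.scr_deletion_len :]
    else:
        del_pos = -1
        scr_b = scr_ref
    block = hairpin["block"]
    mirs3_pad = max(0, 400 - len(block))
    mirs3_block = (
        _random_seq(rng_b, mirs3_pad // 2, comp) + block + _random_seq(rng_b, mirs3_pad - mirs3_pad // 2, comp)
    )
    pieces_b = [
        (None, bg(rng_b, 1000)),
        ("ubox", ubox),
        (None, bg(rng_b, 2800)),
        ("mirs3", mirs3_block),
        (None, bg(rng_b, 2600)),
        ("scr", scr_b),
        (None, bg(rng_b, 3600)),
        ("srk", srk_b),
        (None, bg(rng_b, 11500)),
        ("ark3", ark3),
        (None, bg(rng_b, 2200)),
    ]
    seq_b, coords_b = _assemble(pieces_b)

    # ----- A-like haplotype -----
    rng_a = _rng(cfg.seed, "background_a")
    srk_a = _random_seq(_rng(cfg.seed, "srk_a"), 2500, comp)
    frag_rng = _rng(cfg.seed, "scr_frags")
    frag1 = _degenerate(scr_ref[30:90], frag_rng, 0.2)
    frag2 = _degenerate(scr_ref[180:240], frag_rng, 0.2)
    pieces_a = [
        (None, bg(rng_a, 1000)),
        ("ubox", ubox),
        (None, bg(rng_a, 2800)),
        (None, _random_seq(rng_a, 400, comp)),  # mirS3-sized region, no hairpin
        (None, bg(rng_a, 2600)),
        ("scr_frag1", frag1),
        (None, _random_seq(rng_a, 150, comp)),
        ("scr_frag2", frag2),
        (None, bg(rng_a, 1000)),
        ("target", target_site),
        (None, bg(rng_a, 2700)),
        ("srk", srk_a),
        (None, bg(rng_a, 11500)),
        ("ark3", ark3),
        (None, bg(rng_a, 2200)),
    ]
    seq_a, coords_a = _assemble(pieces_a)

    a_like = LocusSequence(A_ID, seq_a)
    b_like = LocusSequence(B_ID, seq_b)

    hp = cfg.hairpin
    m_start, m_end = coords_b["mirs3"]
    block_start = m_start + mirs3_pad // 2
    left_start = block_start + len(_GUARD)
    left_end = left_start + hp.arm_len
    right_start = left_end + hp.loop_len
    right_end = right_start + len(hairpin["right"])
    srna_start = left_start + hairpin["srna_off"]
    w, x = cfg.target_edits()

    feats = [
        PlantedFeature("ubox_b", B_ID, *coords_b["ubox"]),
        PlantedFeature("mirs3_b", B_ID, m_start, m_end),
        PlantedFeature(
            "precursor_b",
            B_ID,
            left_start,
            right_end,
            attrs={
                "left_arm": (left_start, left_end),
                "right_arm": (right_start, right_end),
                "loop_len": hp.loop_len,
                "paired_len": hp.arm_len - hp.n_mismatches,
                "mismatch_count": hp.n_mismatches,
                "asym_bulge_count": hp.n_bulges,
                "expected_score": hp.expected_ir_score,
            },
        ),
        PlantedFeature(
            "mature_srna",
            B_ID,
            srna_start,
            srna_start + cfg.srna_len,
            attrs={"sequence": hairpin["srna"]},
        ),
        PlantedFeature(
            "scr_b",
            B_ID,
            *coords_b["scr"],
            attrs={
                "deletion_len": cfg.scr_deletion_len,
                "deletion_ref_pos": del_pos,
                "reference_cds": scr_ref,
            },
        ),
        PlantedFeature("srk_b", B_ID, *coords_b["srk"]),
        PlantedFeature("ark3_b", B_ID, *coords_b["ark3"]),
        PlantedFeature("ubox_a", A_ID, *coords_a["ubox"]),
        PlantedFeature("scr_frag1_a", A_ID, *coords_a["scr_frag1"]),
        PlantedFeature("scr_frag2_a", A_ID, *coords_a["scr_frag2"]),
        PlantedFeature(
            "target_a",
            A_ID,
            *coords_a["target"],
            attrs={
                "expected_score": cfg.target_affinity,
                "wobbles": w,
                "mismatches": x,
                "srna": hairpin["srna"],
            },
        ),
        PlantedFeature("srk_a", A_ID, *coords_a["srk"]),
        PlantedFeature("ark3_a", A_ID, *coords_a["ark3"]),
        PlantedFeature("locus_a", A_ID, 0, len(seq_a)),
        PlantedFeature("locus_b", B_ID, 0, len(seq_b)),
    ]
    return a_like, b_like, TruthTable(tuple(feats))


def _assemble(pieces):
    parts = []
    coords = {}
    pos = 0
    for name, seq in pieces:
        if name is not None:
            coords[name] = (pos, pos + len(seq))
        parts.append(seq)
        pos += len(seq)
    return "".join(parts), coords


def _degenerate(seq: str, rng: np.random.Generator, rate: float) -> str:
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            out[i] = rng.choice([b for b in "ACGT" if b != out[i]])
    return "".join(out)


def sample_srna_reads(
    cfg: SyntheticConfig,
    precursor: Interval,
    haplotype: LocusSequence,
    arms: Sequence[Interval] | None = None,
    mature: tuple[int, int] | None = None,
) -> SmallReadSet:
    """Sample expressed small-RNA reads from a precursor, plus background.

    Start positions are uniform over the precursor arms (one length draw per
    position from a 21-24 nt distribution peaked at 24), copy counts are
    Poisson(``srna_depth``) per position. The designated mature sRNA window,
    if given, is emitted at ``srna_depth * mature_enrichment`` expected copies
    (mature-sRNA accumulation). ``background_reads`` singleton reads are drawn
    uniformly from the whole haplotype at 18-27 nt.
    """
    rng = _rng(cfg.seed, "srna_reads")
    lengths = np.array(sorted(_READ_LEN_DIST), dtype=int)
    probs = np.array([_READ_LEN_DIST[int(l)] for l in lengths])
    if arms is None:
        arms = [precursor]
    reads: dict[str, int] = {}

    def add(seq: str, count: int) -> None:
        if count > 0 and seq:
            reads[seq] = reads.get(seq, 0) + count

    for arm in arms:
        for p in range(arm.start, arm.end):
            L = int(rng.choice(lengths, p=probs))
            if p + L > arm.end:
                continue
            add(haplotype.residues[p : p + L], int(rng.poisson(cfg.srna_depth)))
    if mature is not None:
        s, e = mature
        add(haplotype.residues[s:e], int(rng.poisson(cfg.srna_depth * cfg.mature_enrichment)))
    for _ in range(cfg.background_reads):
        L = int(rng.integers(18, 28))
        p = int(rng.integers(0, haplotype.length - L + 1))
        add(haplotype.residues[p : p + L], 1)
    collapsed = tuple(sorted(reads.items()))
    return SmallReadSet(collapsed, 18, 27)


def expected_precursor_copies(cfg: SyntheticConfig, arms: Sequence[Interval], with_mature: bool = True) -> float:
    """Exact expectation of sampled copies starting inside the arms."""
    exp = 0.0
    for arm in arms:
        for L, p in _READ_LEN_DIST.items():
            exp += cfg.srna_depth * p * max(0, len(arm) - L + 1)
    if with_mature:
        exp += cfg.srna_depth * cfg.mature_enrichment
    return exp


def sample_population(cfg: SyntheticConfig = SyntheticConfig()) -> CodingAlignment:
    """Infinite-sites sample: S ~ Poisson(theta * a_n * L) segregating sites,
    each with a derived allele carried by a uniformly chosen proper subset."""
    if cfg.n_samples < 2:
        raise SyntheticConfigError("n_samples must be >= 2")
    rng = _rng(cfg.seed, "population")
    n, L = cfg.n_samples, cfg.pop_length
    ancestral = np.array(list(_random_seq(rng, L, cfg.base_composition)))
    sample = np.tile(ancestral, (n, 1))
    S = int(rng.poisson(cfg.theta_true * watterson_a(n) * L))
    S = min(S, L)
    cols = rng.choice(L, size=S, replace=False)
    sizes = np.arange(1, n)
    size_probs = np.array([comb(n, int(k)) for k in sizes], dtype=float)
    size_probs /= size_probs.sum()
    for col in cols:
        k = int(rng.choice(sizes, p=size_probs))
        rows = rng.choice(n, size=k, replace=False)
        derived = rng.choice([b for b in "ACGT" if b != ancestral[col]])
        sample[rows, col] = derived
    return CodingAlignment(tuple("".join(row) for row in sample))


def write_scenario(cfg: SyntheticConfig, outdir) -> dict:
    """Materialize a full synthetic study scenario on disk.

    Writes the two haplotype FASTAs, the expressed small-RNA reads (FASTA,
    one record per copy), the truth table as GFF3, an infinite-sites
    population alignment and depth tables for both genotype classes. Returns
    the paths plus the in-memory objects.
    """
    from pathlib import Path

    from .io import write_depth_table, write_fasta, write_gff3

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    a_like, b_like, truth = make_haplotype_pair(cfg)
    write_fasta([a_like], out / "haplotype_A.fasta")
    write_fasta([b_like], out / "haplotype_B.fasta")
    prec = truth["precursor_b"]
    arms = [
        Interval(prec.seq_id, *prec.attrs["left_arm"]),
        Interval(prec.seq_id, *prec.attrs["right_arm"]),
    ]
    mature = truth["mature_srna"]
    reads = sample_srna_reads(
        cfg, prec.interval, b_like, arms=arms, mature=(mature.start, mature.end)
    )
    with open(out / "srna_reads.fasta", "w") as fh:
        idx = 0
        for seq, count in reads.reads:
            for _ in range(count):
                fh.write(f">read{idx:06d}\n{seq}\n")
                idx += 1
    write_gff3(
        truth.gff3_rows(), out / "truth.gff3", {a_like.id: a_like.length, b_like.id: b_like.length}
    )
    aln = sample_population(cfg)
    with open(out / "population_alignment.fasta", "w") as fh:
        for i, s in enumerate(aln.sequences):
            fh.write(f">sample{i}\n{s}\n")
    depth_paths = {}
    for genotype in ("A_and_B", "B_only"):
        path = out / f"depth_{genotype}.tsv"
        write_depth_table(make_depth_profile(cfg, genotype, truth), path)
        depth_paths[genotype] = path
    return {
        "a_fasta": out / "haplotype_A.fasta",
        "b_fasta": out / "haplotype_B.fasta",
        "reads_fasta": out / "srna_reads.fasta",
        "truth_gff3": out / "truth.gff3",
        "population_fasta": out / "population_alignment.fasta",
        "depth_tables": depth_paths,
        "a_like": a_like,
        "b_like": b_like,
        "truth": truth,
        "reads": reads,
        "population": aln,
    }


def make_depth_profile(
    cfg: SyntheticConfig, genotype: str, truth: TruthTable | None = None
) -> dict[str, np.ndarray]:
    """Depth tables for both haplotypes under a genotype.

    ``A_and_B``: both haplotypes present, near-uniform Poisson depth.
    ``B_only``: the A-like haplotype receives reads only over its conserved
    U-box/ARK3 flanks (cross-mapping from the shared genes), as for a
    C. orientalis-style control.
    """
    if genotype not in ("A_and_B", "B_only"):
        raise ValueError("genotype must be 'A_and_B' or 'B_only'")
    if truth is None:
        _, _, truth = make_haplotype_pair(cfg)
    rng = _rng(cfg.seed, f"depth_{genotype}")
    lengths = {A_ID: truth["locus_a"].end, B_ID: truth["locus_b"].end}
    out: dict[str, np.ndarray] = {}
    for sid in (A_ID, B_ID):
        L = lengths[sid]
        if genotype == "A_and_B" or sid == B_ID:
            out[sid] = rng.poisson(cfg.depth_mean, size=L).astype(np.int64)
        else:
            arr = np.zeros(L, dtype=np.int64)
            for name in (f"ubox_{'a' if sid == A_ID else 'b'}", f"ark3_{'a' if sid == A_ID else 'b'}"):
                f = truth[name]
                arr[f.start : f.end] = rng.poisson(cfg.depth_mean * 0.7, size=f.end - f.start)
            out[sid] = arr
    return out
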