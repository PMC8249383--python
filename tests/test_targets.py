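import numpy as np
import pytest

from oracles import enumerate_best_duplex_x2, oracle_scan_strand
from sdmod.io import LocusSequence, revcomp
from sdmod.targets import (
    GAP,
    MATCH,
    MISMATCH,
    WOBBLE,
    WobbleScoreScheme,
    _scan_strand,
    merge_hit_regions,
    pair_class,
    scan_targets,
)


def rand_seq(rng, n, alphabet="ACGT"):
    return "".join(rng.choice(list(alphabet), n))


class TestPairClass:
    @pytest.mark.parametrize(
        "pair,expected",
        [
            (("G", "C"), "match"),
            (("A", "T"), "match"),
            (("T", "A"), "match"),
            (("G", "T"), "wobble"),
            (("T", "G"), "wobble"),
            (("A", "A"), "mismatch"),
            (("G", "G"), "mismatch"),
            (("A", "C"), "mismatch"),
            (("N", "A"), "mismatch"),
            (("G", "N"), "mismatch"),
        ],
    )
    def test_classification(self, pair, expected):
        assert pair_class(*pair) == expected

    def test_invalid_base_rejected(self):
        with pytest.raises(ValueError):
            pair_class("G", "U")  # inputs are T-normalized before pairing


class TestKnownScores:
    def test_perfect_complement_scores_srna_length(self):
        rng = np.random.default_rng(0)
        for L in (18, 21, 24, 27):
            srna = rand_seq(rng, L)
            tgt = LocusSequence("t", rand_seq(rng, 80) + revcomp(srna) + rand_seq(rng, 80))
            hits = [h for h in scan_targets(srna, tgt) if h.target.strand == "+"]
            assert len(hits) == 1
            assert hits[0].score == float(L)
            assert hits[0].score_x2 == 2 * L
            assert hits[0].pairing_string == MATCH * L
            assert (hits[0].target.start, hits[0].target.end) == (80, 80 + L)

    def test_17nt_perfect_complement_below_cutoff(self):
        rng = np.random.default_rng(1)
        srna = rand_seq(rng, 17)
        tgt = LocusSequence("t", rand_seq(rng, 50) + revcomp(srna) + rand_seq(rng, 50))
        assert scan_targets(srna, tgt, min_len=17) == []

    def test_18nt_perfect_complement_is_minimum_hit(self):
        rng = np.random.default_rng(2)
        srna = rand_seq(rng, 18)
        tgt = LocusSequence("t", rand_seq(rng, 50) + revcomp(srna) + rand_seq(rng, 50))
        hits = [h for h in scan_targets(srna, tgt) if h.target.strand == "+"]
        assert hits and hits[0].score == 18.0

    def test_21_match_2_wobble_1_mismatch_scores_19(self):
        rng = np.random.default_rng(3)
        while True:
            srna = rand_seq(rng, 24)
            gt = [p for p in range(4, 20) if srna[p] in "GT"]
            if len(gt) >= 3:
                break
        site = list(revcomp(srna))
        for p in gt[:2]:  # wobble: target U opposite sRNA G / target G opposite sRNA U
            site[23 - p] = "T" if srna[p] == "G" else "G"
        mm = gt[2]
        site[23 - mm] = srna[mm]  # identical bases neither pair nor wobble
        tgt = LocusSequence("t", rand_seq(rng, 60) + "".join(site) + rand_seq(rng, 60))
        hits = [h for h in scan_targets(srna, tgt) if h.target.strand == "+"]
        assert len(hits) == 1
        assert hits[0].score_x2 == 38  # exact half-unit arithmetic: 21 - 1 - 1 = 19
        assert hits[0].score == 19.0
        assert sorted(hits[0].pairing_string) == sorted(MATCH * 21 + WOBBLE * 2 + MISMATCH)

    def test_strict_cutoff_comparator(self):
        rng = np.random.default_rng(4)
        srna = rand_seq(rng, 18)
        tgt = LocusSequence("t", rand_seq(rng, 50) + revcomp(srna) + rand_seq(rng, 50))
        assert scan_targets(srna, tgt, WobbleScoreScheme())  # score 18.0 >= 18
        assert scan_targets(srna, tgt, WobbleScoreScheme(strict_cutoff=True)) == []

    def test_length_bounds_enforced(self):
        with pytest.raises(ValueError):
            scan_targets("ACGT" * 7, LocusSequence("t", "ACGT" * 30))  # 28 nt


class TestProperties:
    def test_score_never_exceeds_srna_length(self):
        rng = np.random.default_rng(5)
        scheme = WobbleScoreScheme(cutoff=4.0)
        for _ in range(20):
            srna = rand_seq(rng, int(rng.integers(18, 28)))
            tgt = LocusSequence("t", rand_seq(rng, 300))
            for h in scan_targets(srna, tgt, scheme):
                assert h.score <= len(srna)

    def test_score_equals_pairing_string_arithmetic(self):
        rng = np.random.default_rng(6)
        scheme = WobbleScoreScheme(cutoff=4.0)
        for _ in range(20):
            srna = rand_seq(rng, 20)
            tgt = LocusSequence("t", rand_seq(rng, 200))
            for h in scan_targets(srna, tgt, scheme):
                p = h.pairing_string
                expect = (
                    p.count(MATCH) - 0.5 * p.count(WOBBLE) - p.count(MISMATCH) - 2 * p.count(GAP)
                )
                assert h.score == expect

    def test_revcomp_target_swaps_strands(self):
        rng = np.random.default_rng(7)
        scheme = WobbleScoreScheme(cutoff=6.0)
        srna = rand_seq(rng, 20)
        tgt = LocusSequence("t", rand_seq(rng, 250))
        n = tgt.length
        fwd = scan_targets(srna, tgt, scheme)
        rev = scan_targets(srna, tgt.reverse_complement(), scheme)
        flip = {"+": "-", "-": "+"}
        mirrored = sorted(
            (n - h.target.end, n - h.target.start, flip[h.target.strand], h.score_x2) for h in fwd
        )
        assert sorted((h.target.start, h.target.end, h.target.strand, h.score_x2) for h in rev) == mirrored

    def test_matches_pure_python_dp_oracle(self):
        rng = np.random.default_rng(8)
        scheme = WobbleScoreScheme(cutoff=5.0)
        for _ in range(100):
            m = int(rng.integers(5, 13))
            n = int(rng.integers(10, 41))
            q = rand_seq(rng, m)
            t = "".join(rng.choice(list("ACGTN"), n, p=[0.24] * 4 + [0.04]))
            impl = [(s, a, b) for s, a, b, _ in _scan_strand(q, t, scheme)]
            assert impl == oracle_scan_strand(q, t, scheme)

    def test_best_score_matches_gap_limited_enumeration(self):
        """All start positions x all gap placements up to 2 gaps; the scanner
        must find the enumerated optimum whenever its own optimum needs <=2
        gaps (it may only exceed the enumeration otherwise)."""
        rng = np.random.default_rng(9)
        scheme = WobbleScoreScheme(cutoff=2.0)
        for _ in range(6):
            q = rand_seq(rng, int(rng.integers(8, 13)))
            t = rand_seq(rng, int(rng.integers(20, 41)))
            impl = _scan_strand(q, t, scheme)
            best_impl = max((h[0] for h in impl), default=0)
            best_enum = enumerate_best_duplex_x2(q, t, scheme)
            assert best_impl >= best_enum
            if impl and max(impl, key=lambda h: h[0])[3].count(GAP) <= 2:
                assert best_impl == best_enum


class TestMergeRegions:
    def test_overlapping_hits_merge_keeping_best(self):
        rng = np.random.default_rng(10)
        srna = rand_seq(rng, 24)
        tgt = LocusSequence("t", rand_seq(rng, 50) + revcomp(srna) + rand_seq(rng, 50))
        h24 = scan_targets(("a", srna), tgt)
        h22 = scan_targets(("b", srna[1:23]), tgt, WobbleScoreScheme(cutoff=18.0))
        regions = merge_hit_regions([h for h in h24 + h22 if h.target.strand == "+"])
        assert len(regions) == 1
        iv, best = regions[0]
        assert best.srna_id == "a" and best.score == 24.0
        assert (iv.start, iv.end) == (50, 74)
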