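import numpy as np
import pytest

from sdmod.hairpin import evaluate_hairpin
from sdmod.inverted_repeats import find_inverted_repeats
from sdmod.io import Interval, LocusSequence
from sdmod.popgen import diversity
from sdmod.srna import map_reads, quantify
from sdmod.synth import (
    A_ID,
    B_ID,
    HairpinSpec,
    SyntheticConfig,
    SyntheticConfigError,
    expected_precursor_copies,
    make_depth_profile,
    make_haplotype_pair,
    sample_population,
    sample_srna_reads,
)
from sdmod.annotation import call_frameshifts, classify_coverage
from sdmod.targets import scan_targets


class TestConfigValidation:
    def test_affinity_above_srna_length_rejected(self):
        with pytest.raises(SyntheticConfigError):
            SyntheticConfig(target_affinity=25.0)

    def test_unreachable_affinity_rejected(self):
        # 24 - 1.5*1 = 22.5; asking for 22.0 needs a non-integer mismatch count
        with pytest.raises(SyntheticConfigError):
            SyntheticConfig(target_affinity=22.0, target_wobbles=1)

    def test_deletion_lengths_restricted(self):
        with pytest.raises(SyntheticConfigError):
            SyntheticConfig(scr_deletion_len=5)

    def test_bad_composition_rejected(self):
        with pytest.raises(SyntheticConfigError):
            SyntheticConfig(base_composition=(0.5, 0.5, 0.5, 0.5))


class TestDeterminism:
    def test_haplotypes_and_truth_reproduce(self):
        cfg = SyntheticConfig(seed=17)
        a1, b1, t1 = make_haplotype_pair(cfg)
        a2, b2, t2 = make_haplotype_pair(cfg)
        assert a1.residues == a2.residues
        assert b1.residues == b2.residues
        assert t1 == t2

    def test_reads_population_and_depth_reproduce(self):
        cfg = SyntheticConfig(seed=17)
        _, b, truth = make_haplotype_pair(cfg)
        prec = truth["precursor_b"].interval
        r1 = sample_srna_reads(cfg, prec, b)
        r2 = sample_srna_reads(cfg, prec, b)
        assert r1 == r2
        assert sample_population(cfg) == sample_population(cfg)
        d1 = make_depth_profile(cfg, "B_only", truth)
        d2 = make_depth_profile(cfg, "B_only", truth)
        assert all((d1[k] == d2[k]).all() for k in d1)

    def test_different_seeds_differ(self):
        a1, _, _ = make_haplotype_pair(SyntheticConfig(seed=1))
        a2, _, _ = make_haplotype_pair(SyntheticConfig(seed=2))
        assert a1.residues != a2.residues


class TestPlantedHairpin:
    @pytest.mark.parametrize("seed", [1, 23])
    def test_inverted_repeat_and_metrics_recovered(self, seed):
        cfg = SyntheticConfig(seed=seed)
        _, b, truth = make_haplotype_pair(cfg)
        prec = truth["precursor_b"]
        irs = find_inverted_repeats(b)
        match = [
            ir
            for ir in irs
            if (ir.left_arm.start, ir.left_arm.end) == tuple(prec.attrs["left_arm"])
            and (ir.right_arm.start, ir.right_arm.end) == tuple(prec.attrs["right_arm"])
        ]
        assert len(match) == 1
        ir = match[0]
        assert ir.score == prec.attrs["expected_score"]
        cand = evaluate_hairpin(ir)
        assert cand.loop_len == prec.attrs["loop_len"]
        assert cand.paired_len == prec.attrs["paired_len"]
        assert cand.mismatch_count == prec.attrs["mismatch_count"]
        assert cand.asym_bulge_count == prec.attrs["asym_bulge_count"]
        assert cand.passes

    def test_hairpin_violating_loop_rule_fails_screen(self):
        cfg = SyntheticConfig(seed=5, hairpin=HairpinSpec(loop_len=40))
        _, b, truth = make_haplotype_pair(cfg)
        prec = truth["precursor_b"]
        irs = find_inverted_repeats(b)
        match = [
            ir for ir in irs if (ir.left_arm.start, ir.left_arm.end) == tuple(prec.attrs["left_arm"])
        ]
        assert match and not evaluate_hairpin(match[0]).passes


class TestPlantedTarget:
    def test_perfect_complement_configuration(self):
        cfg = SyntheticConfig(seed=2, target_affinity=24.0, target_wobbles=0)
        a, b, truth = make_haplotype_pair(cfg)
        t = truth["target_a"]
        srna = truth["mature_srna"].attrs["sequence"]
        hits = [h for h in scan_targets(srna, a) if h.target.strand == "+"]
        assert [(h.target.start, h.target.end, h.score) for h in hits] == [(t.start, t.end, 24.0)]

    def test_designed_affinity_19_recovered(self):
        cfg = SyntheticConfig(seed=2)  # 21 match + 2 wobble + 1 mismatch
        a, _, truth = make_haplotype_pair(cfg)
        t = truth["target_a"]
        srna = truth["mature_srna"].attrs["sequence"]
        hits = [h for h in scan_targets(srna, a) if h.target.strand == "+"]
        assert len(hits) == 1
        assert hits[0].score == 19.0
        assert (hits[0].target.start, hits[0].target.end) == (t.start, t.end)
        assert hits[0].pairing_string.count("w") == 2
        assert hits[0].pairing_string.count("x") == 1

    def test_mature_srna_is_genomic_subsequence(self):
        cfg = SyntheticConfig(seed=4)
        _, b, truth = make_haplotype_pair(cfg)
        m = truth["mature_srna"]
        assert b.residues[m.start : m.end] == m.attrs["sequence"]


class TestPlantedScr:
    @pytest.mark.parametrize("dlen", [0, 1, 31])
    def test_deletion_recovered_by_frameshift_caller(self, dlen):
        cfg = SyntheticConfig(seed=6, scr_deletion_len=dlen)
        _, b, truth = make_haplotype_pair(cfg)
        scr = truth["scr_b"]
        cand = LocusSequence("scr_b", b.residues[scr.start : scr.end])
        ref = LocusSequence("ref", scr.attrs["reference_cds"])
        call = call_frameshifts(cand, ref)
        if dlen == 0:
            assert call.status == "intact"
        else:
            assert call.status == "frameshift_pseudogene"
            (indel,) = call.indels
            assert indel.length == dlen
            assert indel.frame_disrupting


class TestReadSampling:
    def test_zero_depth_zero_background_empty(self):
        cfg = SyntheticConfig(seed=3, srna_depth=0.0, background_reads=0)
        _, b, truth = make_haplotype_pair(cfg)
        reads = sample_srna_reads(cfg, truth["precursor_b"].interval, b)
        assert len(reads) == 0

    def test_precursor_count_within_poisson_error(self):
        cfg = SyntheticConfig(seed=8, srna_depth=20.0, background_reads=0)
        _, b, truth = make_haplotype_pair(cfg)
        prec = truth["precursor_b"]
        arms = [Interval(prec.seq_id, *prec.attrs["left_arm"]), Interval(prec.seq_id, *prec.attrs["right_arm"])]
        mat = truth["mature_srna"]
        reads = sample_srna_reads(cfg, prec.interval, b, arms=arms, mature=(mat.start, mat.end))
        mapped = map_reads(reads, [b])
        (expr,) = quantify(mapped, [prec.interval], weight_multimappers=False)
        expect = expected_precursor_copies(cfg, arms)
        assert abs(expr.total_count - expect) <= 3 * np.sqrt(expect)

    def test_read_lengths_within_bounds(self):
        cfg = SyntheticConfig(seed=9)
        _, b, truth = make_haplotype_pair(cfg)
        reads = sample_srna_reads(cfg, truth["precursor_b"].interval, b)
        assert all(18 <= len(s) <= 27 for s, _ in reads.reads)


class TestPopulationSample:
    def test_theta_zero_identical_rows(self):
        aln = sample_population(SyntheticConfig(seed=10, theta_true=0.0))
        assert len(set(aln.sequences)) == 1
        est = diversity(aln)
        assert (est.pi, est.theta_w) == (0.0, 0.0)

    def test_sample_dimensions(self):
        cfg = SyntheticConfig(seed=11, n_samples=6, pop_length=4000)
        aln = sample_population(cfg)
        assert aln.n == 6
        assert aln.L_total == 4000


class TestDepthProfiles:
    def test_genotype_classes(self):
        cfg = SyntheticConfig(seed=12)
        _, _, truth = make_haplotype_pair(cfg)
        both = make_depth_profile(cfg, "A_and_B", truth)
        assert classify_coverage(both[A_ID]).present
        assert classify_coverage(both[B_ID]).present
        b_only = make_depth_profile(cfg, "B_only", truth)
        assert not classify_coverage(b_only[A_ID]).present
        assert classify_coverage(b_only[B_ID]).present

    def test_unknown_genotype_rejected(self):
        with pytest.raises(ValueError):
            make_depth_profile(SyntheticConfig(), "A_only")
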