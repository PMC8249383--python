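import numpy as np
import pytest

from oracles import naive_placements
from sdmod.io import Interval, LocusSequence, SmallReadSet, revcomp
from sdmod.srna import filter_reads, map_reads, quantify


def rand_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), n))


def raw_reads(seqs):
    return SmallReadSet(tuple((s, 1) for s in seqs), 1, max(len(s) for s in seqs))


ADAPTER = "TGGAATTCTCGGGTGCCAAGG"


class TestFilterReads:
    def test_adapter_clipped_and_read_retained(self):
        rng = np.random.default_rng(0)
        insert = rand_seq(rng, 24)
        out = filter_reads(raw_reads([insert + ADAPTER[:10]]), adapter=ADAPTER)
        assert out.reads == ((insert, 1),)

    def test_short_adapter_overlap_not_clipped(self):
        rng = np.random.default_rng(1)
        insert = rand_seq(rng, 20)
        read = insert + ADAPTER[:7]  # 7 < 8 minimum overlap
        out = filter_reads(raw_reads([read]), adapter=ADAPTER)
        assert out.reads == ((read, 1),)

    def test_length_window_enforced(self):
        rng = np.random.default_rng(2)
        r17, r18, r27, r28 = (rand_seq(rng, n) for n in (17, 18, 27, 28))
        out = filter_reads(raw_reads([r17, r18, r27, r28]))
        assert {s for s, _ in out.reads} == {r18, r27}

    def test_identical_reads_collapsed(self):
        rng = np.random.default_rng(3)
        r = rand_seq(rng, 21)
        out = filter_reads(raw_reads([r, r, r]))
        assert out.reads == ((r, 3),)


class TestMapReads:
    def test_exact_forward_placement(self):
        rng = np.random.default_rng(4)
        ref = LocusSequence("ref", rand_seq(rng, 500))
        read = ref.residues[100:124]
        (m,) = map_reads(SmallReadSet(((read, 1),), 18, 27), [ref])
        assert (m.seq_id, m.position, m.strand, m.n_placements) == ("ref", 100, "+", 1)

    def test_reverse_complement_placement(self):
        rng = np.random.default_rng(5)
        ref = LocusSequence("ref", rand_seq(rng, 500))
        read = revcomp(ref.residues[200:222])
        (m,) = map_reads(SmallReadSet(((read, 1),), 18, 27), [ref])
        assert (m.position, m.strand) == (200, "-")

    def test_duplicate_site_counts_placements(self):
        rng = np.random.default_rng(6)
        site = rand_seq(rng, 22)
        ref = LocusSequence("ref", rand_seq(rng, 100) + site + rand_seq(rng, 100) + site + rand_seq(rng, 50))
        ms = map_reads(SmallReadSet(((site, 3),), 18, 27), [ref])
        assert [m.position for m in ms] == [100, 222]
        assert all(m.n_placements == 2 for m in ms)

    def test_agrees_with_naive_scan_oracle(self):
        rng = np.random.default_rng(7)
        refs = [
            LocusSequence("r1", "".join(rng.choice(list("ACGTN"), 800, p=[0.24] * 4 + [0.04]))),
            LocusSequence("r2", rand_seq(rng, 600)),
        ]
        reads = []
        for _ in range(30):  # planted
            ref = refs[rng.integers(2)]
            L = int(rng.integers(18, 28))
            p = int(rng.integers(0, ref.length - L))
            seq = ref.residues[p : p + L]
            reads.append(seq if rng.random() < 0.5 else revcomp(seq))
        reads += [rand_seq(rng, int(rng.integers(18, 28))) for _ in range(10)]
        rs = SmallReadSet(tuple((r, 1) for r in sorted(set(reads))), 18, 27)
        mapped = map_reads(rs, refs)
        got = {}
        for m in mapped:
            got.setdefault(m.read, []).append((m.seq_id, m.position, m.strand))
        ref_dict = {r.id: r.residues for r in refs}
        for seq, _ in rs.reads:
            expected = naive_placements(seq, ref_dict)
            assert sorted(got.get(seq, [])) == expected
            for m in mapped:
                if m.read == seq:
                    assert m.n_placements == len(expected)

    def test_one_mismatch_mode(self):
        rng = np.random.default_rng(8)
        ref = LocusSequence("ref", rand_seq(rng, 300))
        exact = ref.residues[50:72]
        one = "C" + exact[1:] if exact[0] != "C" else "G" + exact[1:]
        two = one[:-1] + ("C" if one[-1] != "C" else "G")
        assert any(m.position == 50 for m in map_reads(SmallReadSet(((one, 1),), 18, 27), [ref], 1))
        assert not any(
            m.position == 50 for m in map_reads(SmallReadSet(((two, 1),), 18, 27), [ref], 1)
        )
        with pytest.raises(ValueError):
            map_reads(SmallReadSet(((exact, 1),), 18, 27), [ref], 2)


class TestQuantify:
    def _setup(self):
        rng = np.random.default_rng(9)
        ref = LocusSequence("ref", rand_seq(rng, 400))
        prec = Interval("ref", 100, 200)
        return rng, ref, prec

    def test_no_overlap_zero_count(self):
        _, ref, prec = self._setup()
        read = ref.residues[300:324]
        mapped = map_reads(SmallReadSet(((read, 5),), 18, 27), [ref])
        (expr,) = quantify(mapped, [prec])
        assert expr.total_count == 0

    def test_copies_and_size_histogram(self):
        _, ref, prec = self._setup()
        read = ref.residues[120:144]
        mapped = map_reads(SmallReadSet(((read, 10),), 18, 27), [ref])
        (expr,) = quantify(mapped, [prec])
        assert expr.total_count == 10
        assert expr.size_histogram[24] == 10
        assert sum(expr.size_histogram.values()) == expr.total_count
        assert expr.coverage[20:44].min() == 10
        assert expr.coverage[0] == 0

    def test_single_base_overlap_counts(self):
        _, ref, prec = self._setup()
        read = ref.residues[181:203]  # overlaps [100,200) by 19 nt at the edge
        edge = ref.residues[199:221]  # 1-nt overlap
        outside = ref.residues[200:222]  # 0-nt overlap
        for read_seq, expect in ((edge, 1), (outside, 0)):
            mapped = map_reads(SmallReadSet(((read_seq, 1),), 18, 27), [ref])
            (expr,) = quantify(mapped, [prec])
            assert expr.total_count == expect

    def test_multimapper_weighting_and_unique_only(self):
        rng = np.random.default_rng(10)
        site = rand_seq(rng, 22)
        ref = LocusSequence("ref", rand_seq(rng, 50) + site + rand_seq(rng, 50) + site + rand_seq(rng, 50))
        mapped = map_reads(SmallReadSet(((site, 4),), 18, 27), [ref])
        p1 = Interval("ref", 50, 72)
        p2 = Interval("ref", 122, 144)
        e1, e2 = quantify(mapped, [p1, p2])
        assert e1.total_count == e2.total_count == 2.0  # 4 copies split over 2 sites
        u1, u2 = quantify(mapped, [p1, p2], unique_only=True)
        assert u1.total_count == u2.total_count == 0.0
        r1, r2 = quantify(mapped, [p1, p2], weight_multimappers=False)
        assert r1.total_count == r2.total_count == 4.0

    def test_disjoint_precursors_never_double_count(self):
        rng = np.random.default_rng(11)
        ref = LocusSequence("ref", rand_seq(rng, 1000))
        reads = tuple(
            (ref.residues[p : p + 22], int(rng.integers(1, 5)))
            for p in rng.integers(0, 978, size=40)
        )
        reads = tuple(dict(reads).items())
        mapped = map_reads(SmallReadSet(reads, 18, 27), [ref])
        # gaps of 30 nt (> max read length) so no read can straddle two precursors
        precs = [Interval("ref", s, s + 70) for s in range(0, 1000, 100)]
        exprs = quantify(mapped, precs, weight_multimappers=True)
        total_mapped = sum(c for _, c in reads)
        assert sum(e.total_count for e in exprs) <= total_mapped + 1e-9
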