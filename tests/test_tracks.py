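import numpy as np
import pytest

from genomering import blastops, seqio, synthetic, tracks
from genomering.errors import ParseError, ValidationError
from genomering.seqio import SequenceRecord
from genomering.tracks import MappingEntry, ValueTrack, track_from_array


def seq(residues, id="s"):
    return SequenceRecord(id=id, description="", residues=residues)


class TestGCContent:
    @pytest.mark.parametrize("residues,window,expected", [
        ("GGCC", 4, [1.0]),
        ("ATAT", 4, [0.0]),
        ("ACGT", 2, [0.5, 0.5]),
    ])
    def test_hand_counts(self, residues, window, expected):
        t = tracks.gc_content(seq(residues), window=window, circular=False)
        assert t.values == expected

    def test_non_acgt_excluded_from_both_sides(self):
        # N excluded entirely: GC of "GCNN" is 2/2
        t = tracks.gc_content(seq("GCNN"), window=4, circular=False)
        assert t.values == [1.0]

    def test_circular_windows_wrap(self):
        # GGAA circular, window 2 step 2: [GG]=1.0, [AA]=0.0
        # window 3 step 3 wraps: [GGA]=2/3, [AGG]... starts at 0 and 3
        t = tracks.gc_content(seq("GGAA"), window=3, step=3, circular=True)
        assert t.values == pytest.approx([2 / 3, 2 / 3])  # AGG wraps to include G,G

    def test_window_longer_than_linear_sequence_errors(self):
        with pytest.raises(ValidationError):
            tracks.gc_content(seq("ACGT"), window=10, circular=False)


class TestGCSkew:
    @pytest.mark.parametrize("residues,expected", [
        ("GGGG", [1.0]),
        ("GGCC", [0.0]),
        ("ATAT", [0.0]),  # zero-denominator convention
    ])
    def test_hand_counts(self, residues, expected):
        t = tracks.gc_skew(seq(residues), window=len(residues), circular=False)
        assert t.values == expected

    def test_complement_negates_skew(self):
        g = synthetic.synth_genome(3_000, 0.5, seed=3)
        comp = seq(g.residues.translate(str.maketrans("ACGT", "TGCA")))
        a = tracks.gc_skew(g, window=300, circular=False).values
        b = tracks.gc_skew(comp, window=300, circular=False).values
        assert a == pytest.approx([-x for x in b])


class TestSkewFromMean:
    def test_equal_width_bins(self):
        t = ValueTrack(bins=((0, 10, 1.0), (10, 20, 2.0), (20, 30, 3.0)),
                       reference_length=30)
        assert tracks.skew_from_mean(t).values == [-1.0, 0.0, 1.0]

    def test_constant_track_goes_flat(self):
        t = ValueTrack(bins=((0, 5, 7.0), (5, 9, 7.0)), reference_length=9)
        assert tracks.skew_from_mean(t).values == [0.0, 0.0]

    def test_output_mean_is_zero_and_idempotent(self):
        rng = np.random.default_rng(12)
        edges = np.sort(rng.choice(np.arange(1, 5000), size=99, replace=False))
        bounds = [0, *edges.tolist(), 5000]
        bins = tuple((bounds[i], bounds[i + 1], float(rng.normal(50, 10)))
                     for i in range(100))
        t = ValueTrack(bins=bins, reference_length=5000)
        centred = tracks.skew_from_mean(t)
        assert abs(centred.mean) < 1e-9
        twice = tracks.skew_from_mean(centred)
        assert twice.values == pytest.approx(centred.values, abs=1e-9)


class TestScaleZeroToMax:
    def test_clamp_and_scale(self):
        t = ValueTrack(bins=((0, 1, 0.0), (1, 2, 15.0), (2, 3, 30.0), (3, 4, 45.0)),
                       reference_length=4)
        assert tracks.scale_zero_to_max(t, 30.0).values == [0.0, 0.5, 1.0, 1.0]

    def test_negative_values_clamp_to_zero(self):
        t = ValueTrack(bins=((0, 1, -5.0),), reference_length=1)
        assert tracks.scale_zero_to_max(t, 10.0).values == [0.0]

    def test_nonpositive_max_rejected(self):
        t = ValueTrack(bins=((0, 1, 1.0),), reference_length=1)
        with pytest.raises(ValidationError):
            tracks.scale_zero_to_max(t, 0.0)


class TestReadGraphFile:
    def test_interval_dialect(self, tmp_path):
        p = tmp_path / "g.txt"
        p.write_text("1 100 5.0\n101 200 7.5\n")
        t = tracks.read_graph_file(p, 200)
        assert t.bins == ((0, 100, 5.0), (100, 200, 7.5))

    def test_per_base_dialect(self, tmp_path):
        p = tmp_path / "g.txt"
        p.write_text("1\n2\n2\n3\n3\n")
        t = tracks.read_graph_file(p, 5)
        assert t.to_array().tolist() == [1, 2, 2, 3, 3]

    def test_per_base_count_mismatch(self, tmp_path):
        p = tmp_path / "g.txt"
        p.write_text("1\n2\n3\n4\n")
        with pytest.raises(ParseError, match="4 values"):
            tracks.read_graph_file(p, 5)

    def test_mixed_column_counts(self, tmp_path):
        p = tmp_path / "g.txt"
        p.write_text("1 100 5.0\n7\n")
        with pytest.raises(ParseError, match="mixed"):
            tracks.read_graph_file(p, 100)


class TestCoverageFromSam:
    def test_single_read_hand_count(self, tmp_path, small_genome, refmap):
        pl = [synthetic.Placement("r1", 4, 10, 1)]
        sam = synthetic.synth_sam(pl, small_genome, tmp_path / "one.sam")
        arr = tracks.coverage_from_sam(sam, refmap).to_array()
        assert arr[4:14].tolist() == [1] * 10
        assert arr.sum() == 10

    def test_overlap_counts_twice(self, tmp_path, small_genome, refmap):
        pl = [synthetic.Placement("r1", 0, 10, 1),
              synthetic.Placement("r2", 7, 10, -1)]
        sam = synthetic.synth_sam(pl, small_genome, tmp_path / "two.sam")
        arr = tracks.coverage_from_sam(sam, refmap).to_array()
        assert arr[7:10].tolist() == [2, 2, 2]
        assert arr[0:7].tolist() == [1] * 7

    def test_thousand_reads_match_bruteforce_pileup(self, tmp_path, small_genome, refmap):
        _reads, pl = synthetic.synth_reads(small_genome, 1_000, 50, seed=21)
        sam = synthetic.synth_sam(pl, small_genome, tmp_path / "many.sam")
        got = tracks.coverage_from_sam(sam, refmap).to_array()
        oracle = synthetic.placement_coverage(pl, small_genome.length)
        assert np.array_equal(got, oracle)

    def test_unmapped_and_secondary_ignored(self, tmp_path, small_genome, refmap):
        sam = tmp_path / "flags.sam"
        sam.write_text(
            f"@HD\tVN:1.6\n@SQ\tSN:{small_genome.id}\tLN:{small_genome.length}\n"
            f"u\t4\t*\t0\t0\t*\t*\t0\t0\t*\t*\n"
            f"sec\t256\t{small_genome.id}\t1\t60\t10M\t*\t0\t0\t*\t*\n"
            f"ok\t0\t{small_genome.id}\t1\t60\t10M\t*\t0\t0\t*\t*\n")
        assert tracks.coverage_from_sam(sam, refmap).to_array().sum() == 10

    def test_deletion_span_not_covered(self, tmp_path, small_genome, refmap):
        sam = tmp_path / "del.sam"
        sam.write_text(
            f"@HD\tVN:1.6\n@SQ\tSN:{small_genome.id}\tLN:{small_genome.length}\n"
            f"d\t0\t{small_genome.id}\t1\t60\t5M3D5M\t*\t0\t0\t*\t*\n")
        arr = tracks.coverage_from_sam(sam, refmap).to_array()
        assert arr[0:5].tolist() == [1] * 5
        assert arr[5:8].tolist() == [0, 0, 0]
        assert arr[8:13].tolist() == [1] * 5


class TestCoverageFromAce:
    def test_mini_ace_hand_pileup(self, mini_ace):
        per_contig, order = tracks.coverage_from_ace(mini_ace)
        assert order == ["contig1"]
        assert per_contig["contig1"].bins == ((0, 8, 1.0), (8, 12, 2.0), (12, 20, 1.0))

    def test_contig_with_zero_reads(self, tmp_path):
        p = tmp_path / "z.ace"
        p.write_text("AS 1 0\n\nCO c1 10 0 0 U\nACGTACGTAC\n\nBQ\n")
        per_contig, _ = tracks.coverage_from_ace(p)
        assert per_contig["c1"].to_array().tolist() == [0.0] * 10

    def test_pad_column_dropped(self, tmp_path):
        p = tmp_path / "pad.ace"
        p.write_text("AS 1 1\n\nCO c1 11 1 0 U\nACGT*ACGTAC\n\nBQ\n\n"
                     "AF r1 U 1\n\nRD r1 11 0 0\nACGT*ACGTAC\n\nQA 1 11 1 11\n")
        per_contig, _ = tracks.coverage_from_ace(p)
        t = per_contig["c1"]
        assert t.reference_length == 10  # padded 11 minus one '*'
        assert t.to_array().tolist() == [1.0] * 10


class TestContigBoundaries:
    def test_alternating_colors_tile_reference(self):
        recs = [seq("A" * 10, "c1"), seq("A" * 20, "c2"), seq("A" * 5, "c3")]
        rm = seqio.build_reference_map(recs)
        segs = tracks.contig_boundaries(rm)
        assert [s[3] for s in segs.segments] == [0, 1, 0]
        assert [(s[0], s[1]) for s in segs.segments] == [(0, 10), (10, 30), (30, 35)]

    def test_single_contig(self):
        rm = seqio.build_reference_map([seq("A" * 10, "only")])
        segs = tracks.contig_boundaries(rm)
        assert [s[3] for s in segs.segments] == [0]


def hit(qstart, qend, sstart, send, bitscore=100.0, aln=None):
    ln = aln or abs(qend - qstart) + 1
    return blastops.BlastHit(query_id="q", subject_id="s", pident=99.0,
                             aln_length=ln, mismatches=0, gapopens=0,
                             qstart=qstart, qend=qend, sstart=sstart,
                             send=send, evalue=1e-30, bitscore=bitscore)


class TestMappingFromBlast:
    def test_forward_hit(self):
        (m,) = tracks.mapping_from_blast([hit(1, 100, 201, 300)])
        assert (m.old_start, m.old_end, m.new_start, m.new_end, m.orientation) == \
            (0, 100, 200, 300, 1)

    def test_inverted_subject_gives_minus(self):
        (m,) = tracks.mapping_from_blast([hit(1, 100, 300, 201)])
        assert m.orientation == -1

    def test_gapped_hit_truncated_to_shorter_span(self):
        (m,) = tracks.mapping_from_blast([hit(1, 100, 201, 298)])
        assert m.old_end - m.old_start == m.new_end - m.new_start == 98
        assert (m.old_start, m.new_start) == (0, 200)


class TestRemapTrack:
    def _random_track(self, n, seed):
        rng = np.random.default_rng(seed)
        return track_from_array(rng.integers(0, 50, size=n).astype(float))

    def test_identity_mapping_is_identity(self):
        t = self._random_track(400, 31)
        mapping = (MappingEntry(0, 400, 0, 400, 1, 10.0),)
        out = tracks.remap_track(t, mapping, 400)
        assert np.array_equal(out.to_array(), t.to_array())

    def test_two_block_swap_matches_bruteforce_transport(self):
        t = self._random_track(400, 32)
        mapping = (MappingEntry(0, 200, 200, 400, 1, 10.0),
                   MappingEntry(200, 400, 0, 200, 1, 10.0))
        out = tracks.remap_track(t, mapping, 400).to_array()
        old = t.to_array()
        oracle = np.zeros(400)
        for e in mapping:  # brute-force per-base transport
            for i in range(e.old_end - e.old_start):
                oracle[e.new_start + i] = old[e.old_start + i]
        assert np.array_equal(out, oracle)

    def test_reversed_block_reverses_values(self):
        t = self._random_track(100, 33)
        mapping = (MappingEntry(0, 100, 0, 100, -1, 5.0),)
        out = tracks.remap_track(t, mapping, 100).to_array()
        assert np.array_equal(out, t.to_array()[::-1])

    def test_highest_score_wins_on_overlap(self):
        t = track_from_array(np.arange(10, dtype=float))
        mapping = (MappingEntry(0, 10, 0, 10, 1, 1.0),
                   MappingEntry(5, 10, 0, 5, 1, 9.0))
        out = tracks.remap_track(t, mapping, 10).to_array()
        assert out[:5].tolist() == [5, 6, 7, 8, 9]
        assert out[5:].tolist() == [5, 6, 7, 8, 9]

    def test_mass_conserved_under_bijective_mapping(self):
        t = self._random_track(600, 34)
        mapping = (MappingEntry(0, 300, 300, 600, 1, 1.0),
                   MappingEntry(300, 600, 0, 300, -1, 1.0))
        out = tracks.remap_track(t, mapping, 600)
        assert out.to_array().sum() == pytest.approx(t.to_array().sum())


class TestCoverageAnomalies:
    def test_constant_track_has_none(self):
        t = track_from_array(np.full(100, 7.0))
        assert tracks.coverage_anomalies(t, 1.0) == []

    def test_single_spike_recovered_exactly(self):
        arr = np.full(10_000, 100.0)
        arr[4_000:4_500] = 300.0
        t = track_from_array(arr)
        assert tracks.coverage_anomalies(t, 1.0) == [(4_000, 4_500)]

    def test_huge_k_empty(self):
        rng = np.random.default_rng(35)
        t = track_from_array(rng.normal(100, 10, size=1000))
        assert tracks.coverage_anomalies(t, 1e9) == []

    def test_bed_output_is_half_open(self, tmp_path):
        p = tracks.write_bed([(10, 20), (30, 40)], tmp_path / "a.bed")
        lines = [l.split("\t") for l in p.read_text().splitlines()]
        assert [(int(l[1]), int(l[2])) for l in lines] == [(10, 20), (30, 40)]
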