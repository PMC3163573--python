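import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from genomering import ringmodel, seqio, synthetic, tracks
from genomering.blastops import BlastHit
from genomering.errors import ValidationError
from genomering.ringmodel import RingSpec
from genomering.tracks import ValueTrack


def hit(sstart, send, pident=100.0, bitscore=100.0):
    ln = abs(send - sstart) + 1
    return BlastHit(query_id="q", subject_id="s", pident=pident, aln_length=ln,
                    mismatches=0, gapopens=0, qstart=1, qend=ln, sstart=sstart,
                    send=send, evalue=1e-30, bitscore=bitscore)


class TestIdentityToOpacity:
    @pytest.mark.parametrize("pident,expected", [
        (100.0, 1.0),
        (70.0, 0.1),     # lower endpoint: the minimum visible opacity
        (85.0, 0.55),    # linear midpoint: 0.1 + 0.9 * 0.5
        (69.9, None),    # below the threshold the hit is omitted
    ])
    def test_gradient_values(self, pident, expected):
        got = ringmodel.identity_to_opacity(pident, 70.0, 100.0)
        if expected is None:
            assert got is None
        else:
            assert got == pytest.approx(expected)

    @settings(derandomize=True, max_examples=100)
    @given(st.floats(min_value=70, max_value=100),
           st.floats(min_value=70, max_value=100))
    def test_monotone_on_kept_range(self, a, b):
        lo, hi = min(a, b), max(a, b)
        o1 = ringmodel.identity_to_opacity(lo, 70.0, 100.0)
        o2 = ringmodel.identity_to_opacity(hi, 70.0, 100.0)
        assert o1 <= o2

    def test_continuous_at_upper(self):
        just_below = ringmodel.identity_to_opacity(99.999999, 70.0, 100.0)
        assert ringmodel.identity_to_opacity(100.0, 70.0, 100.0) - just_below < 1e-5


class TestBuildBlastRing:
    @pytest.fixture
    def refmap(self):
        return seqio.build_reference_map(
            [seqio.SequenceRecord("ref", "", "A" * 10_000)])

    def spec(self, **kw):
        base = dict(kind="blast", members=("a",), lower_identity=70.0,
                    upper_identity=100.0)
        base.update(kw)
        return RingSpec(**base)

    def test_empty_hit_sets_give_no_arcs(self, refmap):
        assert ringmodel.build_blast_ring([("a", [])], self.spec(), refmap) == []

    def test_full_reference_hit_is_one_opaque_arc(self, refmap):
        arcs = ringmodel.build_blast_ring([("a", [hit(1, 10_000)])], self.spec(), refmap)
        assert [(a.start, a.end, a.opacity) for a in arcs] == [(0, 10_000, 1.0)]

    def test_collation_pools_members_and_z_follows_bitscore(self, refmap):
        rng = np.random.default_rng(7)
        sets = []
        for name in ("a", "b", "c"):
            hits = [hit(int(s) + 1, int(s) + 100, bitscore=float(rng.integers(10, 500)))
                    for s in rng.integers(0, 9_000, size=10)]
            sets.append((name, hits))
        arcs = ringmodel.build_blast_ring(
            sets, self.spec(members=("a", "b", "c")), refmap)
        assert len(arcs) == 30
        zs = [a.z for a in arcs]
        assert zs == sorted(zs)
        # z order must follow ascending bitscore of the pooled hits
        pooled = sorted((h for _n, hs in sets for h in hs), key=lambda h: h.bitscore)
        assert [a.start for a in arcs] == [h.sstart - 1 for h in pooled]

    def test_hits_below_lower_identity_omitted(self, refmap):
        hits = [hit(1, 100, pident=60.0), hit(200, 300, pident=70.0)]
        arcs = ringmodel.build_blast_ring([("a", hits)], self.spec(), refmap)
        assert [(a.start, a.end) for a in arcs] == [(199, 300)]

    def test_unloaded_member_rejected(self, refmap):
        with pytest.raises(ValidationError, match="no loaded data"):
            ringmodel.build_blast_ring([("a", [])], self.spec(members=("a", "zzz")),
                                       refmap)

    def test_wrap_split_conserves_length(self):
        parts = ringmodel.split_wrapping(900, 1100, 1000)
        assert parts == [(900, 1000), (0, 100)]
        assert sum(e - s for s, e in parts) == 200


class TestBuildGraphRing:
    def test_constant_track_is_flat_zero(self):
        t = ValueTrack(bins=((0, 5, 3.0), (5, 10, 3.0)), reference_length=10)
        prof = ringmodel.build_graph_ring(t, RingSpec(kind="graph", members=("g",)))
        assert [b[2] for b in prof.bins] == [0.0, 0.0]

    def test_mean_skew_scales_peak_to_one(self):
        t = ValueTrack(bins=((0, 1, 1.0), (1, 2, 3.0), (2, 3, 5.0)), reference_length=3)
        prof = ringmodel.build_graph_ring(t, RingSpec(kind="graph", members=("g",)))
        assert [b[2] for b in prof.bins] == pytest.approx([-1.0, 0.0, 1.0])

    def test_zero_to_max_mode(self):
        t = ValueTrack(bins=((0, 1, 0.0), (1, 2, 15.0), (2, 3, 30.0), (3, 4, 45.0)),
                       reference_length=4)
        spec = RingSpec(kind="graph", members=("g",), graph_mode="zero_to_max",
                        graph_max=30.0)
        prof = ringmodel.build_graph_ring(t, spec)
        assert [b[2] for b in prof.bins] == [0.0, 0.5, 1.0, 1.0]


class TestAssemble:
    def test_zero_rings_still_builds(self):
        rm = seqio.build_reference_map([seqio.SequenceRecord("r", "", "A" * 100)])
        model = ringmodel.assemble(rm, [], {}, title="bare")
        assert model.rings == ()
        assert model.tick_major > 0

    def test_draft_genome_shaped_model(self):
        """Structure of a full draft-assembly image: GC rings, coverage,
        contigs, four collated BLAST rings, and an annotation ring."""
        contigs = [synthetic.synth_genome(2_000 + 100 * i, 0.5, seed=i, id=f"c{i}")
                   for i in range(5)]
        rm = seqio.build_reference_map(contigs)
        concat = seqio.concatenate(contigs)
        cov = tracks.track_from_array(np.full(rm.total_length, 30.0))
        hits = [hit(1, 500, bitscore=50.0)]
        data = {
            "gc": tracks.gc_content(concat, window=500),
            "skew": tracks.gc_skew(concat, window=500),
            "cov": cov,
            "ctg": tracks.contig_boundaries(rm),
            "q1": hits, "q2": hits, "q3": hits, "q4": hits,
            "ann": seqio.header_annotations(rm),
        }
        specs = [
            RingSpec(kind="graph", members=("skew",), color="#7700aa"),
            RingSpec(kind="graph", members=("gc",), color="#000000"),
            RingSpec(kind="graph", members=("cov",), color="#8b5a2b",
                     graph_mode="zero_to_max", graph_max=100.0),
            RingSpec(kind="contigs", members=("ctg",)),
            RingSpec(kind="blast", members=("q1",)),
            RingSpec(kind="blast", members=("q2",)),
            RingSpec(kind="blast", members=("q3", "q4"), legend_text="collated"),
            RingSpec(kind="annotations", members=("ann",)),
        ]
        model = ringmodel.assemble(rm, specs, data)
        assert len(model.rings) == 8
        assert [r.spec.kind for r in model.rings] == [
            "graph", "graph", "graph", "contigs", "blast", "blast", "blast",
            "annotations"]
        assert len(model.legend) == 3  # one entry per BLAST ring

    def test_shared_member_allowed_dangling_rejected(self):
        rm = seqio.build_reference_map([seqio.SequenceRecord("r", "", "A" * 1000)])
        data = {"q": [hit(1, 100)]}
        specs = [RingSpec(kind="blast", members=("q",)),
                 RingSpec(kind="blast", members=("q",))]
        model = ringmodel.assemble(rm, specs, data)
        assert all(len(r.arcs) == 1 for r in model.rings)
        with pytest.raises(ValidationError, match="ghost"):
            ringmodel.assemble(rm, [RingSpec(kind="blast", members=("ghost",))], data)

    def test_assemble_is_deterministic(self):
        rm = seqio.build_reference_map([seqio.SequenceRecord("r", "", "A" * 1000)])
        data = {"q": [hit(1, 100, bitscore=50), hit(200, 400, bitscore=70)]}
        specs = [RingSpec(kind="blast", members=("q",))]
        assert ringmodel.assemble(rm, specs, data) == ringmodel.assemble(rm, specs, data)


class TestRingSpecInvariants:
    def test_identity_bounds(self):
        with pytest.raises(ValidationError):
            RingSpec(kind="blast", members=("a",), lower_identity=90, upper_identity=80)

    def test_only_blast_collates(self):
        with pytest.raises(ValidationError):
            RingSpec(kind="graph", members=("a", "b"))
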