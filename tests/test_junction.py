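"""Joining rules, SW3 re-alignment, TGN calling, orientation and bonus."""

import numpy as np
import pytest

from tirmap import InsertionMapper, ReferenceDatabase
from tirmap.alignment import GPA, TPA, PartialAlignment, score_alignment
from tirmap.junction import (
    Border,
    FinalAlignment,
    apply_bonus,
    classify_orientation,
    resolve_overlap,
    sw3_realign,
)
from tirmap.params import AlignmentParams
from tirmap.refdb import EncodedReference, reverse_complement
from tirmap.seeding import FORWARD
from tirmap.simulate import (
    MutationSpec,
    apply_mutation,
    make_insertion_pair,
    make_junction_reads,
    make_self_insertion_read,
)

from conftest import random_seq

P = AlignmentParams()


def _pa(kind, q_start, pattern, name="r", strand=FORWARD, score=None):
    """PA from a column pattern of M (match) / X (mismatch), gap-free."""
    q = "".join("A" if c == "M" else "C" for c in pattern)
    r = "".join("A" if c == "M" else "G" for c in pattern)
    ns = "transposon" if kind == TPA else "genomic"
    pa = PartialAlignment(
        kind, name, ns, strand, q_start, q_start + len(pattern) - 1,
        1, len(pattern), q, r,
        score if score is not None else 2.0 * pattern.count("M") - pattern.count("X"),
    )
    from tirmap.alignment import find_nucleus

    pa.nucleus = find_nucleus(pa, 10)
    return pa


class TestResolveOverlap:
    def test_nucleus_trims_partner_tail(self):
        left = _pa(TPA, 1, "M" * 30)                 # nucleus covers q1..30
        right = _pa(GPA, 25, "X" * 6 + "M" * 30)     # 6-column tail overlaps it
        assert resolve_overlap(left, right, P) == 30  # GPA trimmed by 6

    def test_nucleus_overlap_within_40pct_goes_to_tpa(self):
        left = _pa(TPA, 1, "M" * 20)     # nucleus length 20
        right = _pa(GPA, 16, "M" * 15)   # nucleus length 15, overlap 5
        # 5/20 = 25 %, 5/15 = 33 % <= 40 %: joinable, shared columns to TPA
        assert resolve_overlap(left, right, P) == 20

    def test_nucleus_overlap_beyond_40pct_refused(self):
        left = _pa(TPA, 1, "M" * 15)
        right = _pa(GPA, 9, "M" * 15)    # overlap 7: 7/15 = 46 % > 40 %
        assert resolve_overlap(left, right, P) is None

    def test_same_kind_dispute_goes_to_higher_score(self):
        left = _pa(GPA, 1, "M" * 20, score=40.0)
        right = _pa(GPA, 17, "M" * 20, score=60.0)   # overlap 4, right wins
        assert resolve_overlap(left, right, P) == 16
        right.score, left.score = 10.0, 60.0
        assert resolve_overlap(left, right, P) == 20

    def test_tail_tail_split_maximises_kept_score(self):
        # left ends with mismatch tail, right begins with matches: the split
        # lands so the mismatching left columns are given up
        left = _pa(GPA, 1, "M" * 20 + "X" * 5)
        right = _pa(GPA, 21, "M" * 25)
        assert resolve_overlap(left, right, P) == 20

    def test_non_overlapping_pairs_rejected(self):
        with pytest.raises(ValueError):
            resolve_overlap(_pa(GPA, 1, "M" * 12), _pa(GPA, 50, "M" * 12), P)


class TestSW3:
    def test_window_elongated_ten_each_side(self):
        rng = np.random.default_rng(1)
        refseq = random_seq(155, rng)
        ref = EncodedReference("g", "genomic", refseq)
        query = refseq[89:155]  # ref coords 90..155
        pa = PartialAlignment(
            GPA, "g", "genomic", FORWARD, 1, len(query), 100, 150,
            query[10:61], refseq[99:150], 0.0,
        )
        out = sw3_realign(pa, query, ref, P, (1, len(query)))
        # window [100-10, 150+10] clamped to [90, 155] reaches both ends
        assert (out.ref_start, out.ref_end) == (90, 155)
        assert out.score == 2.0 * 66

    def test_left_clamp_at_reference_start(self):
        rng = np.random.default_rng(2)
        refseq = random_seq(60, rng)
        ref = EncodedReference("g", "genomic", refseq)
        query = refseq[:40]
        pa = PartialAlignment(
            GPA, "g", "genomic", FORWARD, 1, 40, 5, 40,
            query[4:40], refseq[4:40], 0.0,
        )
        out = sw3_realign(pa, query, ref, P, (1, 40))
        assert out.ref_start == 1  # only 4 nt of left extension existed

    def test_snp_near_tgn_reincluded_as_terminal_match(self, small_world, small_mapper):
        """A SNP at TSD position 2 leaves the TGN beyond a mismatch; the
        SW3 re-alignment recovers it as a terminal match."""
        read = make_junction_reads(small_world, 1, layout="tir_genome", seed=40)[0]
        mutated = apply_mutation(read, MutationSpec("snp_transversion", (2,)), seed=1)
        res = small_mapper.map_query(mutated.sequence, "snp2")
        assert res.call.tgn_coordinate == mutated.truth_coordinate
        gpa = [s for s in res.best.segments if s.kind == GPA][0]
        assert gpa.ref_start == mutated.truth_coordinate
        assert gpa.match_columns()[0]          # TGN is a terminal match
        assert not gpa.match_columns()[1]      # followed by the planted SNP


class TestAssembly:
    def test_clean_composite_two_segments_no_tpa_tail(self, small_world, small_mapper):
        read = make_junction_reads(small_world, 1, layout="tir_genome", seed=41)[0]
        res = small_mapper.map_query(read.sequence, "clean")
        fa = res.best
        assert [s.kind for s in fa.segments] == [TPA, GPA]
        tpa, gpa = fa.segments
        # the TPA cannot exceed the construct margin beyond the TIR
        assert tpa.terminal_ref_coords()[1] == len(small_world.construct)
        assert fa.borders[0].tir_terminal == len(small_world.construct)
        assert fa.coverage(len(read.sequence)) == 1.0
        assert res.call.tgn_coordinate == read.truth_coordinate

    def test_pure_genomic_query_single_gpa(self, small_world, small_mapper):
        query = small_world.genome[8000:8300]
        res = small_mapper.map_query(query, "genomic")
        fa = res.best
        assert len(fa.segments) == 1 and fa.segments[0].kind == GPA
        assert fa.borders == []
        assert res.call.call_kind == "genomic_only"

    def test_two_border_read_three_segments_double_bonus(self, small_world, small_db):
        read = make_junction_reads(small_world, 1, layout="tir_genome_tir", seed=42)[0]
        mapper = InsertionMapper(small_db, P.with_(bonus_enabled=True))
        res = mapper.map_query(read.sequence, "twoborder")
        fa = res.best
        assert len(fa.segments) == 3 and len(fa.borders) == 2
        assert all(b.is_transposon_genome for b in fa.borders)
        assert fa.total_score == fa.sw_score + 2 * P.bonus
        assert res.call.tgn_coordinate == read.truth_coordinate

    def test_score_consistency_with_rescoring_oracle(self, small_world, small_mapper):
        read = make_junction_reads(small_world, 1, layout="tir_genome", seed=43)[0]
        fa = small_mapper.map_query(read.sequence, "q").best
        total = sum(
            score_alignment(s.aligned_query, s.aligned_ref, P) for s in fa.segments
        )
        assert fa.sw_score == total
        assert fa.total_score == fa.sw_score  # bonus off by default

    def test_unmappable_query_reported_not_fatal(self, small_mapper):
        res = small_mapper.map_query("ACGTACGTACGTACGTACGT"[:12], "tiny")
        # 12 nt of sequence absent from the references
        assert res.unmappable or res.call is not None
        res2 = small_mapper.map_query("ACGTA", "too-short")
        assert res2.unmappable and res2.call is None


class TestCalling:
    def test_tgn_is_first_genomic_coordinate_after_border(self, small_world, small_mapper):
        read = make_junction_reads(small_world, 1, layout="tir_genome", seed=44)[0]
        res = small_mapper.map_query(read.sequence, "q")
        gpa = [s for s in res.best.segments if s.kind == GPA][0]
        assert res.call.tgn_coordinate == gpa.ref_coord_at_col(1) == read.truth_coordinate

    def test_paired_reads_differ_by_tsd_minus_one(self, small_world, small_mapper):
        five, three = make_insertion_pair(small_world, seed=45)
        r5 = small_mapper.map_query(five.sequence, "five")
        r3 = small_mapper.map_query(three.sequence, "three")
        assert r5.call.tgn_coordinate - r3.call.tgn_coordinate == small_world.tsd_length - 1 == 7

    def test_self_insertion_called_with_internal_coordinate(self, small_world, small_mapper):
        read = make_self_insertion_read(small_world, seed=46)
        res = small_mapper.map_query(read.sequence, "self")
        assert res.call.call_kind == "self_insertion"
        assert res.call.tgn_coordinate == read.truth_coordinate
        m0, m1 = small_world.marker_span
        assert m0 <= res.call.tgn_coordinate <= m1
        assert "marker" in res.call.affected_features

    def test_non_terminus_border_flagged_low_confidence(self, small_world, small_mapper):
        # transposon fragment taken from the construct interior: the border
        # is not at a TIR terminus but the coordinate is still reported
        c, g = small_world.construct, small_world.genome
        read = c[200:320] + g[12000:12160]
        res = small_mapper.map_query(read, "lowconf")
        assert res.call.call_kind == "genomic_insertion"
        assert res.call.low_confidence
        assert res.call.tgn_coordinate == 12001


class TestOrientation:
    @pytest.mark.parametrize(
        "layout,orientation,expected",
        [
            ("tir_genome", "type_I", ("type_I", "three_prime")),     # r-> b->
            ("genome_tir", "type_I", ("type_I", "five_prime")),      # b-> r->
            ("tir_genome", "type_II", ("type_II", "five_prime")),    # <-r b->
            ("genome_tir", "type_II", ("type_II", "three_prime")),   # b-> <-r
        ],
    )
    def test_table_of_configurations(self, small_world, small_mapper, layout, orientation, expected):
        read = make_junction_reads(
            small_world, 1, layout=layout, orientation=orientation, seed=47
        )[0]
        res = small_mapper.map_query(read.sequence, "q")
        assert (res.call.orientation, res.call.sequenced_end) == expected
        assert res.call.tgn_coordinate == read.truth_coordinate

    def test_reverse_complement_preserves_classification(self, small_world, small_mapper):
        for layout in ("tir_genome", "genome_tir"):
            read = make_junction_reads(small_world, 1, layout=layout, seed=48)[0]
            a = small_mapper.map_query(read.sequence, "fwd").call
            b = small_mapper.map_query(reverse_complement(read.sequence), "rc").call
            assert (a.orientation, a.sequenced_end) == (b.orientation, b.sequenced_end)
            assert a.tgn_coordinate == b.tgn_coordinate


class TestBonus:
    def _fa(self, kinds):
        segs = [_pa(k, 1 + 30 * i, "M" * 20) for i, k in enumerate(kinds)]
        borders = [
            Border(i, i + 1, 0, 0, kinds[i], kinds[i + 1]) for i in range(len(kinds) - 1)
        ]
        sw = sum(s.score for s in segs)
        return FinalAlignment(segs, borders, sw, sw)

    def test_bonus_adds_500_per_transposon_genome_border(self):
        fa = apply_bonus(self._fa([TPA, GPA]), P.with_(bonus_enabled=True))
        assert fa.total_score == fa.sw_score + 500 and fa.bonus_applied

    def test_bonus_disabled_leaves_score(self):
        fa = apply_bonus(self._fa([TPA, GPA]), P.with_(bonus_enabled=False))
        assert fa.total_score == fa.sw_score and not fa.bonus_applied

    def test_self_insertion_border_never_bonused(self):
        fa = apply_bonus(self._fa([TPA, TPA]), P.with_(bonus_enabled=True))
        assert fa.total_score == fa.sw_score and not fa.bonus_applied

    def test_bonus_flips_marker_self_insertion_and_warns(self, small_world, small_db):
        read = make_self_insertion_read(small_world, seed=49)
        off = InsertionMapper(small_db, P.with_(bonus_enabled=False))
        on = InsertionMapper(small_db, P.with_(bonus_enabled=True))
        assert off.map_query(read.sequence, "q").call.call_kind == "self_insertion"
        res_on = on.map_query(read.sequence, "q")
        assert res_on.call.call_kind == "genomic_insertion"  # the false positive
        assert any("bonus" in w for w in res_on.warnings)


class TestBorderMotif:
    @pytest.mark.parametrize("trial", range(4))
    def test_shared_motif_assigned_to_transposon(self, trial):
        """A k-nt motif shared by the TIR terminus and the genomic flank is
        kept on the transposon side: the TGN is the coordinate after it."""
        rng = np.random.default_rng(300 + trial)
        genome = random_seq(3000, rng)
        t = int(rng.integers(1000, 1800))
        construct = random_seq(500, rng)[:-4] + genome[t - 5 : t - 1]
        db = ReferenceDatabase()
        db.register("g", genome, "genomic")
        db.register("c", construct, "transposon")
        read = construct[-120:] + genome[t - 1 : t + 139]
        res = InsertionMapper(db).map_query(read, f"motif{trial}")
        assert res.call.tgn_coordinate == t          # after the motif,
        assert res.call.tgn_coordinate != t - 4      # never before it
        assert res.call.tir_terminal_coordinate == 500


def test_classify_orientation_requires_single_qualified_border():
    seg = _pa(GPA, 1, "M" * 20)
    fa = FinalAlignment([seg], [], seg.score, seg.score)
    with pytest.raises(ValueError):
        classify_orientation(fa)
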