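"""Alignment post-processing rules and chain selection.

The chain-selection DP is checked against exhaustive subset
enumeration (an independent brute-force oracle) on random constructed
segment sets.
"""

import numpy as np
import pytest

from oracles import best_chain_bruteforce

from tcrbseq.annotate import (
    AlignedSegment,
    AlignParams,
    Aligner,
    align_read,
    build_chain,
    fix_c_order,
    merge_broken,
    split_overlap_at_splice,
)
from tcrbseq.locus import GeneSegment, LocusModel
from tcrbseq.preprocess import ProcessedRead
from tcrbseq.simulate import CategoryMix, revcomp, simulate_insert


def seg(rs, re_, fs, fe, strand="+", identity=1.0, label="", kind=""):
    return AlignedSegment(rs, re_, fs, fe, strand, identity, label, kind)


class TestMergeBroken:
    """|d_read - d_ref| < max(d_read, d_ref)/2, both gaps small."""

    def _case(self, locus, d_r, d_g):
        # read = ref block with a d_r-bp spacer replacing a d_g-bp ref gap
        ref0 = 1000
        a_len, b_len = 40, 48
        read = (
            locus.subseq(ref0, ref0 + a_len)
            + "N" * d_r
            + locus.subseq(ref0 + a_len + d_g, ref0 + a_len + d_g + b_len)
        )
        segs = [
            seg(0, a_len, ref0, ref0 + a_len),
            seg(a_len + d_r, a_len + d_r + b_len, ref0 + a_len + d_g, ref0 + a_len + d_g + b_len),
        ]
        return read, segs

    @pytest.mark.parametrize(
        "d_r, d_g, merged",
        [
            (10, 12, True),  # |2| < 6
            (5, 20, False),  # 15 >= 10
            (0, 0, True),  # abutting fragments rejoin
            (10, 16, True),  # |6| < 8
            (10, 15, True),  # |5| < 7.5
            (10, 20, False),  # |10| >= 10
        ],
    )
    def test_merge_rule(self, locus, d_r, d_g, merged):
        read, segs = self._case(locus, d_r, d_g)
        out = merge_broken(segs, read, locus)
        assert (len(out) == 1) == merged
        if merged:
            assert out[0].read_start == 0 and out[0].ref_end == segs[-1].ref_end

    def test_gap_beyond_close_threshold_not_merged(self, locus):
        read, segs = self._case(locus, 40, 42)
        assert len(merge_broken(segs, read, locus, close_threshold=30)) == 2

    def test_idempotent_and_never_shrinks_alignment(self, locus):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = rng.integers(2, 5)
            pos, ref = 0, 500
            segs = []
            for _ in range(n):
                ln = int(rng.integers(20, 60))
                segs.append(seg(pos, pos + ln, ref, ref + ln))
                pos += ln + int(rng.integers(0, 40))
                ref += ln + int(rng.integers(0, 40))
            read = "A" * pos
            before = sum(s.read_len for s in segs)
            once = merge_broken(list(segs), read, locus)
            twice = merge_broken(list(once), read, locus)
            assert [vars(s) for s in once] == [vars(s) for s in twice]
            assert sum(s.read_len for s in once) >= before


class TestFixCOrder:
    def _c_intervals(self, locus):
        return locus.segment("C1"), locus.segment("C2")

    def test_out_of_order_c1_relabeled_c2(self, locus):
        c1, c2 = self._c_intervals(locus)
        j2 = locus.segment("J2-3")
        segs = [
            seg(0, 50, j2.start, j2.end, label="J2-3", kind="J"),
            seg(50, 150, c1.start, c1.start + 100, label="C1", kind="C"),
        ]
        out = fix_c_order(segs, locus)
        assert out[1].label == "C2"
        assert out[1].ref_start == c2.start
        assert len(out) == len(segs)

    def test_ordered_c1_unchanged(self, locus):
        c1 = locus.segment("C1")
        j1 = locus.segment("J1-1")
        segs = [
            seg(0, 50, j1.start, j1.end, label="J1-1", kind="J"),
            seg(50, 150, c1.start, c1.start + 100, label="C1", kind="C"),
        ]
        out = fix_c_order(segs, locus)
        assert out[1].label == "C1"

    def test_c1_only_chain_unchanged(self, locus):
        c1 = locus.segment("C1")
        segs = [seg(0, 100, c1.start, c1.start + 100, label="C1", kind="C")]
        assert fix_c_order(segs, locus)[0].label == "C1"

    def test_never_relabels_c2_to_c1(self, locus):
        c2 = locus.segment("C2")
        v = locus.segment("V1")
        segs = [
            seg(0, 100, c2.start, c2.start + 100, label="C2", kind="C"),
            seg(100, 200, v.start, v.start + 100, label="V1", kind="V"),
        ]
        out = fix_c_order(segs, locus)
        assert [s.label for s in out] == ["C2", "V1"]


class TestSplitOverlap:
    def test_overlap_split_at_gt_ag_junction(self, locus):
        j = locus.segment("J2-3")
        c2 = locus.segment("C2")
        jlen = len(j)
        read = locus.subseq(j.start, j.end) + locus.subseq(c2.start, c2.start + 60)
        segs = [
            seg(0, jlen + 3, j.start, j.end + 3),
            seg(jlen - 3, jlen + 60, c2.start - 3, c2.start + 60),
        ]
        out = split_overlap_at_splice(segs, locus, read)
        assert out[0].read_end == out[1].read_start == jlen
        assert out[0].ref_end == j.end  # GT donor immediately after
        assert out[1].ref_start == c2.start  # AG acceptor immediately before
        assert not out[0].flags

    def test_no_candidate_midpoint_and_flag(self):
        loc = LocusModel("A" * 400, [GeneSegment("V1", "V", 0, 10)])
        segs = [seg(0, 30, 10, 40), seg(24, 60, 100, 136)]
        out = split_overlap_at_splice(segs, loc, "A" * 60)
        assert out[0].read_end == out[1].read_start == 27
        assert "no_splice_support" in out[0].flags

    def test_zero_overlap_unchanged(self, locus):
        segs = [seg(0, 30, 10, 40), seg(30, 60, 100, 130)]
        out = split_overlap_at_splice(segs, locus, "A" * 60)
        assert out[0].read_end == 30 and out[1].read_start == 30

    def test_large_overlap_treated_as_alternatives(self, locus):
        segs = [seg(0, 100, 10, 110), seg(2, 98, 1000, 1096)]
        out = split_overlap_at_splice(segs, locus, "A" * 100, max_overlap=30)
        assert out[0].read_end == 100 and out[1].read_start == 2


class TestChainSelection:
    def test_ordered_segments_chain_fully(self, locus):
        segs = [
            seg(0, 100, 200, 300, label="V1", kind="V"),
            seg(100, 130, 2680, 2710, label="D1", kind="D"),
            seg(130, 180, 2810, 2860, label="J1-1", kind="J"),
            seg(180, 280, 3260, 3360, label="C1", kind="C"),
        ]
        chain = build_chain(segs, "A" * 280, locus)
        assert len(chain.segments) == 4 and not chain.conflicts

    def test_cross_strand_conflict_retained(self, locus):
        segs = [
            seg(0, 100, 200, 300, strand="+"),
            seg(120, 200, 3300, 3380, strand="-"),
        ]
        chain = build_chain(segs, "A" * 200, locus)
        assert len(chain.segments) == 1
        assert len(chain.conflicts) == 1 and chain.conflicts[0].strand == "-"

    def test_near_duplicate_alternative_not_a_conflict(self, locus):
        segs = [
            seg(0, 100, 3260, 3360, identity=0.99),  # C1 placement
            seg(0, 100, 4370, 4470, identity=1.0),  # C2 placement, better
        ]
        chain = build_chain(segs, "A" * 100, locus)
        assert chain.segments[0].ref_start == 4370
        assert not chain.conflicts

    def test_empty_input_rejected(self, locus):
        with pytest.raises(ValueError):
            build_chain([], "A" * 10, locus)

    def test_matches_bruteforce_enumeration_on_1000_random_cases(self, locus):
        rng = np.random.default_rng(7)
        params = AlignParams()
        for _ in range(1000):
            n = int(rng.integers(1, 5))
            segs = []
            for _ in range(n):
                rs = int(rng.integers(0, 150))
                ln = int(rng.integers(20, 60))
                fs = int(rng.integers(0, 2000))
                strand = "+" if rng.random() < 0.8 else "-"
                ident = float(rng.choice([1.0, 0.95, 0.9]))
                segs.append(seg(rs, rs + ln, fs, fs + ln, strand, ident))
            chain = build_chain(segs, "A" * 300, locus, params)
            got = (
                sum(s.score for s in chain.segments),
                len(chain.segments),
                -chain.segments[0].read_start,
            )
            expected = best_chain_bruteforce(segs, params.chain_slack)
            assert got == pytest.approx(expected)

    def test_equal_score_tie_prefers_more_segments_then_leftmost(self, locus):
        # one 100 bp segment vs two 50 bp segments: equal score
        segs = [
            seg(0, 50, 100, 150),
            seg(50, 100, 300, 350),
            seg(0, 100, 1000, 1100),
        ]
        chain = build_chain(segs, "A" * 100, locus)
        assert len(chain.segments) == 2
        # leftmost: two equal single-segment options
        segs2 = [seg(10, 60, 100, 150), seg(20, 70, 1000, 1050)]
        chain2 = build_chain(segs2, "A" * 100, locus)
        assert chain2.segments[0].read_start == 10


class TestEndToEndAlignment:
    def test_error_free_nr_read_yields_intron_j_then_c(self, locus, aligner, rng):
        insert, t = simulate_insert(locus, "NR", rng)
        chain = align_read(ProcessedRead("r", "S", insert, (0, len(insert))), aligner)
        assert [s.kind for s in chain.segments] == ["J", "C"]
        assert chain.segments[0].upstream_intron_bp == t.intron_len
        assert chain.segments[0].label == t.j_name

    def test_minus_strand_read_reported_on_minus(self, locus, aligner, rng):
        insert, t = simulate_insert(locus, "NR", rng)
        chain = align_read(ProcessedRead("r", "S", revcomp(insert), (0, len(insert))), aligner)
        assert chain.strand == "-"
        assert [s.kind for s in chain.segments] == ["J", "C"]

    def test_random_sequence_unannotatable(self, aligner, rng):
        junk = "".join(rng.choice(list("ACGT"), size=300))
        assert align_read(ProcessedRead("r", "S", junk, (0, 300)), aligner) is None

    def test_cr_v_j_names_match_truth(self, locus, aligner, rng):
        mix = CategoryMix(v_only_prob=0.0)
        hits = 0
        for _ in range(50):
            insert, t = simulate_insert(locus, "CR", rng, mix)
            chain = align_read(ProcessedRead("r", "S", insert, (0, len(insert))), aligner)
            names = {s.kind: s.label for s in chain.segments}
            hits += names.get("V") == t.v_name and names.get("J") == t.j_name
        assert hits >= 50 * 0.99
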