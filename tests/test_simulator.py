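"""Constructive correctness of simulated inserts, technical layout,
error process, and cohort pooling."""

import numpy as np
import pytest

from tcrbseq.simulate import (
    ADAPTER1,
    ADAPTER2,
    UPM,
    CATEGORIES,
    CategoryMix,
    ClonalSpike,
    ErrorModel,
    SampleDesign,
    apply_errors,
    attach_technical,
    default_barcodes,
    revcomp,
    simulate_cohort,
    simulate_insert,
)


class TestInsertStructure:
    """Each category's insert satisfies its defining structural rule."""

    def test_unknown_category_rejected(self, locus, rng):
        with pytest.raises(ValueError, match="unknown category"):
            simulate_insert(locus, "XX", rng)

    @pytest.mark.parametrize("category", CATEGORIES)
    def test_insert_is_deterministic_per_state(self, locus, category):
        a = simulate_insert(locus, category, np.random.default_rng(3))[0]
        b = simulate_insert(locus, category, np.random.default_rng(3))[0]
        assert a == b

    def test_nr_insert_starts_in_upstream_intron(self, locus, rng):
        for _ in range(20):
            insert, t = simulate_insert(locus, "NR", rng)
            j = locus.segment(t.j_name)
            assert t.intron_len >= 15
            start = j.start - t.intron_len
            assert insert.startswith(locus.subseq(start, j.end))
            c = locus.segment(t.c_name)
            assert insert[j.end - start :] == locus.subseq(c.start, c.start + len(insert) - (j.end - start))

    def test_nr_j22p_subtype_covers_pseudogene(self, locus, rng):
        mix = CategoryMix(j22p_prob=1.0, nr_j23_weight=1.0 - 1e-9)
        j22p = locus.segment("J2-2P")
        j23 = locus.segment("J2-3")
        for _ in range(10):
            insert, t = simulate_insert(locus, "NR", rng, mix)
            assert t.subtype == "J2-2P~J2-3"
            assert j23.start - t.intron_len < j22p.end  # alignment covers J2-2P

    def test_pr_insert_has_intron_before_d(self, locus, rng):
        insert, t = simulate_insert(locus, "PR", rng)
        d = locus.segment(t.d_name)
        assert t.intron_len >= 15
        assert insert.startswith(locus.subseq(d.start - t.intron_len, d.end))

    def test_cr_insert_is_v_junction_j_c(self, locus, rng):
        mix = CategoryMix(v_only_prob=0.0)
        insert, t = simulate_insert(locus, "CR", rng, mix)
        v, j, c = locus.segment(t.v_name), locus.segment(t.j_name), locus.segment(t.c_name)
        v_end = insert.find(t.cdr3_seq + locus.subseq(j.start, j.end))
        assert v_end > 0  # V part, then junction, then full J
        assert locus.subseq(v.end - v_end, v.end) == insert[:v_end]
        assert 6 <= len(t.cdr3_seq) <= 50  # random junction, optionally with a D core

    def test_ns_insert_is_intron_plus_c(self, locus, rng):
        insert, t = simulate_insert(locus, "NS", rng)
        c = locus.segment(t.c_name)
        assert t.intron_len >= 15
        assert insert == locus.subseq(c.start - t.intron_len, c.start - t.intron_len + len(insert))

    def test_ar_insert_ends_within_30bp_of_cryptic_rss(self, locus, rng):
        rss = next(r for r in locus.rss_sites if r.cryptic)
        for _ in range(10):
            insert, t = simulate_insert(locus, "AR", rng)
            j = locus.segment(t.j_name)
            i_len = insert.find(locus.subseq(j.start, j.end))
            # the intergenic prefix ends i_len into the insert
            end = rss.start - t.intron_len
            assert insert[:i_len] == locus.subseq(end - i_len, end)
            assert 0 <= t.intron_len <= 30

    def test_ch_two_c_variant_contains_both_c_segments(self, locus, rng):
        while True:
            insert, t = simulate_insert(locus, "CH", rng)
            if t.subtype == "C-J-C":
                break
        c1, c2 = locus.segment("C1"), locus.segment("C2")
        assert locus.subseq(c1.start, c1.start + 80) in insert
        assert locus.subseq(c2.start, c2.start + 80) in insert

    def test_uc_insert_has_short_intron(self, locus, rng):
        insert, t = simulate_insert(locus, "UC", rng)
        assert t.intron_len < 15

    def test_clonal_spike_is_reproducible_clonotype(self, locus, rng):
        spike = ClonalSpike("V2", "J2-1", "ACGTACGTACGT", 0.5)
        a, ta = simulate_insert(locus, "CR", rng, spike=spike)
        assert ta.cdr3_seq == "ACGTACGTACGT"
        assert ta.v_name == "V2" and ta.j_name == "J2-1"


class TestTechnicalLayout:
    def test_read_wraps_insert_with_adapters_and_barcodes(self):
        bc = "ACGTACGTAC"
        read = attach_technical("TTTT", bc)
        assert read == ADAPTER1 + bc + UPM + "TTTT" + revcomp(bc) + revcomp(ADAPTER2)

    def test_empty_insert_gives_technical_only_read(self):
        bc = "ACGTACGTAC"
        read = attach_technical("", bc)
        assert len(read) == len(ADAPTER1) + len(ADAPTER2) + 2 * len(bc) + len(UPM)

    def test_wrong_barcode_length_rejected(self):
        with pytest.raises(ValueError, match="barcode"):
            attach_technical("TTTT", "ACGTACGT")


class TestErrorModel:
    def test_zero_rates_identity(self, rng):
        read = "ACGT" * 100
        assert apply_errors(read, ErrorModel(0, 0), rng) == read

    def test_rates_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            ErrorModel(0.5, 0)

    def test_same_seed_same_output(self):
        read = "ACGTTGCA" * 200
        model = ErrorModel(0.02, 0.01)
        a = apply_errors(read, model, np.random.default_rng(9))
        b = apply_errors(read, model, np.random.default_rng(9))
        assert a == b and a != read

    def test_substitution_count_within_3_sigma_of_binomial(self):
        n, rate = 100_000, 0.01
        read = "A" * n
        out = apply_errors(read, ErrorModel(rate, 0.0), np.random.default_rng(11))
        subs = sum(b != "A" for b in out)
        sigma = (n * rate * (1 - rate)) ** 0.5
        assert abs(subs - n * rate) < 3 * sigma


class TestCohort:
    def test_mix_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            CategoryMix(proportions={"CR": 0.5, "NR": 0.4}).validate()

    def test_spike_cannot_exceed_cr_fraction(self):
        mix = CategoryMix(clonal_spike=ClonalSpike("V1", "J1-1", "AAAA", 0.9))
        with pytest.raises(ValueError, match="clonal_spike"):
            mix.validate()

    def test_duplicate_barcode_rejected(self, locus):
        bc = default_barcodes(1)[0]
        samples = [
            SampleDesign("A", bc, CategoryMix(), 5),
            SampleDesign("B", bc, CategoryMix(), 5),
        ]
        with pytest.raises(ValueError, match="duplicate barcode"):
            simulate_cohort(locus, samples)

    def test_close_barcodes_rejected(self, locus):
        samples = [
            SampleDesign("A", "ACGTACGTAC", CategoryMix(), 5),
            SampleDesign("B", "ACGTACGTAG", CategoryMix(), 5),
        ]
        with pytest.raises(ValueError, match="Hamming"):
            simulate_cohort(locus, samples)

    def test_default_barcodes_pairwise_distant(self):
        codes = default_barcodes(8)
        for i, a in enumerate(codes):
            for b in codes[i + 1 :]:
                assert sum(x != y for x, y in zip(a, b)) >= 3

    def test_requested_proportions_recovered(self, locus):
        mix = CategoryMix(proportions={"NR": 0.85, "CR": 0.15})
        samples = [SampleDesign("S1", default_barcodes(1)[0], mix, 1000)]
        _, truth = simulate_cohort(locus, samples, seed=2)
        n_nr = (truth.category == "NR").sum()
        assert 800 <= n_nr <= 900  # >0.999 coverage interval for Bin(1000, .85)

    def test_rerun_same_seed_identical(self, locus):
        samples = [SampleDesign("S1", default_barcodes(1)[0], CategoryMix(), 50)]
        ra, ta = simulate_cohort(locus, samples, ErrorModel(0.01, 0.002), seed=4)
        rb, tb = simulate_cohort(locus, samples, ErrorModel(0.01, 0.002), seed=4)
        assert [str(x.seq) for x in ra] == [str(x.seq) for x in rb]
        assert ta.equals(tb)
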