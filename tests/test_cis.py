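"""Locus parsing, TSS distances, the 50-kb screen, and pair summaries.

The nearest-edge distance oracle is an exhaustive scan over every base of
the lncRNA interval; the screen oracle is an all-pairs recomputation.
"""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cislnc.cis import (
    classify_pair,
    format_locus,
    pair_distance,
    parse_locus,
    screen_cis_pairs,
    summarize_pairs,
)
from cislnc.errors import DataError
from cislnc.simulate import generate_correlated_fold_changes
from cislnc.types import CisPair, DEResult, TranscriptRecord


def _tx(tid, start, end, strand="+", biotype="lncRNA", chrom="chr1"):
    return TranscriptRecord(
        transcript_id=tid,
        gene_id=f"g_{tid}",
        biotype=biotype,
        chrom=chrom,
        start=start,
        end=end,
        strand=strand,
    )


def _de(tid, log2fc, comparison="B_vs_A"):
    return DEResult(
        transcript_id=tid,
        comparison=comparison,
        log2fc=log2fc,
        fold_change=2.0**log2fc,
        p=0.001,
        q=0.001,
        status="OK",
    )


class TestParseLocus:
    def test_printed_locus_converts_to_half_open(self):
        chrom, start, end = parse_locus("chr11:65266530-65273915")
        assert (chrom, start, end) == ("chr11", 65266529, 65273915)
        assert end - start == 7386  # printed interval length in bp

    def test_round_trip_to_printed_string(self, table1):
        for locus in table1["locus_hg19"]:
            assert format_locus(*parse_locus(locus)) == locus

    def test_single_base_interval(self):
        assert parse_locus("chr1:1-1") == ("chr1", 0, 1)

    @pytest.mark.parametrize("bad", ["chr1:10-5", "chr1:0-5", "chr1-10:5", "x", "chr1:a-b"])
    def test_malformed_locus_rejected(self, bad):
        with pytest.raises(DataError):
            parse_locus(bad)


class TestPairDistance:
    def test_tss_inside_lncrna_gives_zero(self):
        lnc = _tx("l", 1000, 2000)
        mrna = _tx("m", 1500, 3000, biotype="mRNA")
        assert pair_distance(lnc, mrna) == 0

    def test_nearest_edge_gap_downstream_of_lnc(self):
        # documented sign convention: lncRNA before a + strand TSS is upstream
        lnc = _tx("l", 1000, 2000)
        mrna = _tx("m", 2500, 4000, biotype="mRNA")
        assert pair_distance(lnc, mrna) == -500

    def test_gap_beyond_screen_magnitude(self):
        lnc = _tx("l", 1000, 2000)
        mrna = _tx("m", 60_001, 62_000, biotype="mRNA")
        assert abs(pair_distance(lnc, mrna)) == 58_001

    def test_sign_flips_with_mrna_orientation(self):
        lnc = _tx("l", 1000, 2000)
        plus = _tx("m1", 2500, 4000, biotype="mRNA", strand="+")
        minus = _tx("m2", 100, 2500 + 1, biotype="mRNA", strand="-")  # TSS at 2500
        assert pair_distance(lnc, plus) == -500
        assert pair_distance(lnc, minus) == 500

    def test_cross_chromosome_is_none(self):
        lnc = _tx("l", 0, 100, chrom="chr1")
        mrna = _tx("m", 0, 100, biotype="mRNA", chrom="chr2")
        assert pair_distance(lnc, mrna) is None

    def test_tss5p_anchor_uses_lnc_five_prime_end(self):
        lnc = _tx("l", 1000, 2000, strand="-")  # 5' end at 1999
        mrna = _tx("m", 2500, 4000, biotype="mRNA")
        assert abs(pair_distance(lnc, mrna, anchor="tss5p")) == 501

    @given(
        start=st.integers(0, 300),
        length=st.integers(1, 120),
        tss=st.integers(0, 500),
        lnc_strand=st.sampled_from("+-"),
        mrna_strand=st.sampled_from("+-"),
    )
    def test_magnitude_matches_exhaustive_base_scan(
        self, start, length, tss, lnc_strand, mrna_strand
    ):
        lnc = _tx("l", start, start + length, strand=lnc_strand)
        if mrna_strand == "+":
            mrna = _tx("m", tss, tss + 50, strand="+", biotype="mRNA")
        else:
            mrna = _tx("m", max(0, tss - 49), tss + 1, strand="-", biotype="mRNA")
        oracle = min(abs(mrna.tss - x) for x in range(lnc.start, lnc.end + 1))
        assert abs(pair_distance(lnc, mrna)) == oracle

    @given(shift=st.integers(0, 10_000_000))
    def test_translation_invariance(self, shift):
        lnc = _tx("l", 1000 + shift, 2000 + shift)
        mrna = _tx("m", 2500 + shift, 4000 + shift, biotype="mRNA")
        assert pair_distance(lnc, mrna) == -500


class TestClassifyPair:
    @pytest.mark.parametrize(
        "l,m,expected",
        [
            (-2.0, -1.8, "co_down"),
            (1.7, 2.2, "co_up"),
            (1.6, -1.9, "opposite"),
            (-1.6, 1.9, "opposite"),
        ],
    )
    def test_patterns_follow_sign_combination(self, l, m, expected):
        assert classify_pair(l, m) == expected

    def test_zero_fold_change_rejected(self):
        with pytest.raises(DataError):
            classify_pair(0.0, 1.0)


class TestScreen:
    def test_planted_pairs_and_only_those_survive(self, zero_noise_annotation, zero_noise_sim):
        from cislnc.diffexpr import filter_de
        from cislnc.diffexpr import test_de as run_de_test

        ann, sim = zero_noise_annotation, zero_noise_sim
        results = run_de_test(sim.matrix, "Islet", "ALT")
        screened = filter_de(results, "cis_screen").retained
        biotype = sim.de_truth.set_index("transcript_id")["biotype"]
        pairs = screen_cis_pairs(
            [r for r in screened if biotype[r.transcript_id] == "lncRNA"],
            [r for r in screened if biotype[r.transcript_id] == "mRNA"],
            ann.by_id(),
        )
        assert {(p.lnc_id, p.mrna_id) for p in pairs} == ann.planted_pair_ids()

    def test_zero_max_distance_keeps_only_tss_overlaps(self):
        ann = {
            "l1": _tx("l1", 1000, 2000),
            "l2": _tx("l2", 5000, 6000),
            "m1": _tx("m1", 1500, 3000, biotype="mRNA"),
        }
        pairs = screen_cis_pairs(
            [_de("l1", 2.0), _de("l2", 2.0)], [_de("m1", -2.0)], ann, max_distance=0
        )
        assert [(p.lnc_id, p.mrna_id) for p in pairs] == [("l1", "m1")]
        assert pairs[0].signed_distance == 0

    def test_missing_annotation_names_the_transcript(self):
        with pytest.raises(DataError, match="ghost"):
            screen_cis_pairs([_de("ghost", 2.0)], [], {})

    @given(data=st.data())
    def test_matches_brute_force_all_pairs_oracle(self, data):
        n_lnc = data.draw(st.integers(1, 8), label="n_lnc")
        n_mrna = data.draw(st.integers(1, 8), label="n_mrna")
        ann, de_lnc, de_mrna = {}, [], []
        for i in range(n_lnc):
            s = data.draw(st.integers(0, 200_000), label=f"ls{i}")
            ann[f"l{i}"] = _tx(f"l{i}", s, s + data.draw(st.integers(1, 5_000)))
            de_lnc.append(_de(f"l{i}", 2.0))
        for i in range(n_mrna):
            s = data.draw(st.integers(0, 200_000), label=f"ms{i}")
            strand = data.draw(st.sampled_from("+-"), label=f"mstr{i}")
            ann[f"m{i}"] = _tx(
                f"m{i}", s, s + data.draw(st.integers(1, 5_000)), strand=strand,
                biotype="mRNA",
            )
            de_mrna.append(_de(f"m{i}", -2.0))
        cutoff = data.draw(st.sampled_from([0, 1_000, 50_000]), label="cutoff")
        got = {
            (p.lnc_id, p.mrna_id)
            for p in screen_cis_pairs(de_lnc, de_mrna, ann, max_distance=cutoff)
        }
        expect = set()
        for rl in de_lnc:
            for rm in de_mrna:
                d = pair_distance(ann[rl.transcript_id], ann[rm.transcript_id])
                if d is not None and abs(d) <= cutoff:
                    expect.add((rl.transcript_id, rm.transcript_id))
        assert got == expect

    def test_raising_max_distance_never_removes_pairs(self, zero_noise_annotation, zero_noise_sim):
        from cislnc.diffexpr import filter_de
        from cislnc.diffexpr import test_de as run_de_test

        ann, sim = zero_noise_annotation, zero_noise_sim
        screened = filter_de(run_de_test(sim.matrix, "Islet", "ALT"), "cis_screen").retained
        biotype = sim.de_truth.set_index("transcript_id")["biotype"]
        lnc = [r for r in screened if biotype[r.transcript_id] == "lncRNA"]
        mrna = [r for r in screened if biotype[r.transcript_id] == "mRNA"]
        small = {
            (p.lnc_id, p.mrna_id)
            for p in screen_cis_pairs(lnc, mrna, ann.by_id(), max_distance=20_000)
        }
        big = {
            (p.lnc_id, p.mrna_id)
            for p in screen_cis_pairs(lnc, mrna, ann.by_id(), max_distance=130_000)
        }
        assert small <= big


def _pair(l2_lnc, l2_mrna, i=0):
    return CisPair(
        lnc_id=f"l{i}",
        mrna_id=f"m{i}",
        chrom="chr1",
        signed_distance=100,
        lnc_log2fc=l2_lnc,
        mrna_log2fc=l2_mrna,
        pattern=classify_pair(l2_lnc, l2_mrna),
        antisense_flag=False,
    )


class TestSummarize:
    def test_counts_partition_pairs(self):
        pairs = [
            _pair(-2, -2, 0),
            _pair(-1.6, -3, 1),
            _pair(2, 2, 2),
            _pair(2, -2, 3),
        ]
        s = summarize_pairs(pairs, "B_vs_A")
        assert (s.n_co_down, s.n_co_up, s.n_opposite) == (2, 1, 1)
        assert s.n_pairs == 4

    def test_collinear_pairs_give_unit_correlation(self):
        pairs = [_pair(x, 2 * x + 0.5, i) for i, x in enumerate([1.0, 2.0, 3.0, 4.0])]
        s = summarize_pairs(pairs)
        assert s.pearson_r == pytest.approx(1.0)

    def test_single_pair_correlation_flagged_undefined(self):
        s = summarize_pairs([_pair(-2, -2)])
        assert s.n_pairs == 1 and s.pearson_r is None and not s.correlation_defined

    def test_planted_correlation_recovered_within_confidence_interval(self):
        x, y = generate_correlated_fold_changes(0.5, 400, seed=17)
        x, y = x + np.sign(x) * 0.01, y + np.sign(y) * 0.01  # keep nonzero
        pairs = [_pair(xi, yi, i) for i, (xi, yi) in enumerate(zip(x, y))]
        s = summarize_pairs(pairs)
        # 95% CI of r-hat via the Fisher z transform must cover the planted 0.5
        z = np.arctanh(s.pearson_r)
        half = 1.96 / np.sqrt(400 - 3)
        assert np.tanh(z - half) < 0.5 < np.tanh(z + half)
        assert s.p_two_tailed < 1e-4

    @given(
        a=st.floats(min_value=0.1, max_value=10),
        b=st.floats(min_value=-5, max_value=5),
    )
    def test_correlation_invariant_under_positive_affine_transform(self, a, b):
        base = [(-2.0, -1.5), (1.7, 2.2), (2.5, -1.8), (-3.0, 2.0), (1.6, 1.9)]
        pairs = [_pair(x, y, i) for i, (x, y) in enumerate(base)]
        transformed = [
            CisPair(
                lnc_id=p.lnc_id,
                mrna_id=p.mrna_id,
                chrom=p.chrom,
                signed_distance=p.signed_distance,
                lnc_log2fc=a * p.lnc_log2fc + b,
                mrna_log2fc=p.mrna_log2fc,
                pattern=p.pattern,
                antisense_flag=p.antisense_flag,
            )
            for p in pairs
        ]
        r0 = summarize_pairs(pairs).pearson_r
        r1 = summarize_pairs(transformed).pearson_r
        assert r1 == pytest.approx(r0, abs=1e-9)
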