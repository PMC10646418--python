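"""Fold changes, the replicate t-test, threshold presets, and Fisher
enrichment, checked against closed forms and brute-force oracles."""

import math
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cislnc.diffexpr import (
    PRESETS,
    ThresholdPreset,
    compute_log2fc,
    enrichment_fisher,
    filter_de,
    frame_to_results,
    results_to_frame,
)
from cislnc.diffexpr import test_de as run_de_test
from cislnc.errors import DataError
from cislnc.matrix import ExpressionMatrix
from cislnc.types import DEResult


def _matrix(values: dict, groups: dict) -> ExpressionMatrix:
    frame = pd.DataFrame(values).T
    frame.columns = [f"s{i}" for i in range(frame.shape[1])]
    samples = pd.DataFrame(
        {
            "sample": frame.columns,
            "group": [groups[c] for c in frame.columns],
            "replicate": list(range(frame.shape[1])),
        }
    )
    return ExpressionMatrix(frame, samples)


def _two_group(a_vals, b_vals):
    n_a, n_b = len(a_vals[0]), len(b_vals[0])
    values = {f"t{i}": list(a) + list(b) for i, (a, b) in enumerate(zip(a_vals, b_vals))}
    groups = {f"s{i}": ("A" if i < n_a else "B") for i in range(n_a + n_b)}
    return _matrix(values, groups)


class TestLog2fc:
    def test_islet_graft_fpkm_ratio_matches_arithmetic(self):
        # lnc-CTRB1-1:1: islet mean 60.2895, ALT graft mean 1.48629
        m = _two_group([[60.2895]], [[1.48629]])
        l2 = compute_log2fc(m, "A", "B", pseudocount=0.0)
        assert l2["t0"] == pytest.approx(math.log2(1.48629 / 60.2895), abs=1e-12)
        assert l2["t0"] == pytest.approx(-5.3421, abs=1e-4)

    def test_identical_means_give_zero(self):
        m = _two_group([[5.0, 5.0]], [[5.0, 5.0]])
        assert compute_log2fc(m, "A", "B")["t0"] == 0.0

    def test_pseudocount_closed_form_with_zero_mean(self):
        m = _two_group([[0.0]], [[7.0]])
        assert compute_log2fc(m, "A", "B", pseudocount=1.0)["t0"] == pytest.approx(3.0)

    def test_zero_pseudocount_with_zero_mean_is_signalled_infinite(self):
        m = _two_group([[0.0]], [[7.0]])
        assert np.isinf(compute_log2fc(m, "A", "B", pseudocount=0.0)["t0"])

    def test_absent_group_errors(self):
        m = _two_group([[1.0]], [[2.0]])
        with pytest.raises(DataError):
            compute_log2fc(m, "A", "C")

    @given(
        st.lists(
            st.floats(min_value=0.01, max_value=1e4), min_size=4, max_size=4
        ),
        st.floats(min_value=0.0, max_value=10.0),
    )
    def test_antisymmetry_under_group_swap(self, vals, pc):
        m = _two_group([vals[:2]], [vals[2:]])
        ab = compute_log2fc(m, "A", "B", pc)["t0"]
        ba = compute_log2fc(m, "B", "A", pc)["t0"]
        assert ab == pytest.approx(-ba, abs=1e-9)


class TestStudentStandIn:
    def test_identical_replicates_give_p_one_and_zero_log2fc(self):
        m = _two_group([[3.0, 3.0, 3.0]], [[3.0, 3.0, 3.0]])
        (r,) = run_de_test(m, "A", "B")
        assert r.p == 1.0 and r.log2fc == 0.0 and r.status == "OK"

    def test_single_replicate_group_is_lowdata(self):
        m = _two_group([[3.0]], [[4.0, 5.0]])
        (r,) = run_de_test(m, "A", "B")
        assert r.status == "LOWDATA"
        assert math.isnan(r.p)

    def test_zero_noise_planted_truth_recovered_exactly(self, zero_noise_sim):
        sim = zero_noise_sim
        results = run_de_test(sim.matrix, "Islet", "ALT")
        filtered = filter_de(results, "rnaseq_de")
        truth = sim.de_truth.set_index("transcript_id")["direction"]
        assert {r.transcript_id for r in filtered.up} == set(truth[truth == "up"].index)
        assert {r.transcript_id for r in filtered.down} == set(
            truth[truth == "down"].index
        )

    def test_null_type_i_error_calibrated_at_five_percent(self):
        # 10,000 null transcripts, 3 vs 3, log2 noise sd 0.3
        rng = np.random.default_rng(123)
        log2 = rng.normal(4.0, 0.3, size=(10_000, 6))
        frame = pd.DataFrame(
            2.0**log2,
            index=[f"t{i}" for i in range(10_000)],
            columns=[f"s{i}" for i in range(6)],
        )
        samples = pd.DataFrame(
            {
                "sample": frame.columns,
                "group": ["A"] * 3 + ["B"] * 3,
                "replicate": [1, 2, 3, 1, 2, 3],
            }
        )
        results = run_de_test(ExpressionMatrix(frame, samples), "A", "B", pseudocount=0.0)
        frac = np.mean([r.p < 0.05 for r in results])
        assert frac == pytest.approx(0.05, abs=0.01)

    def test_bh_q_dominates_p_and_is_monotone_in_p_rank(self, noisy_sim):
        results = run_de_test(noisy_sim.matrix, "Islet", "ALT")
        ps = np.array([r.p for r in results])
        qs = np.array([r.q for r in results])
        assert (qs >= ps - 1e-12).all()
        order = np.argsort(ps)
        assert (np.diff(qs[order]) >= -1e-12).all()


def _result(log2fc=0.0, p=1.0, q=1.0, status="OK", tid="t", comparison="B_vs_A"):
    return DEResult(
        transcript_id=tid,
        comparison=comparison,
        log2fc=log2fc,
        fold_change=2.0**log2fc,
        p=p,
        q=q,
        status=status,
    )


class TestFilterPresets:
    def test_rnaseq_boundary_is_inclusive(self):
        r = _result(log2fc=1.0, p=0.01, q=0.05)
        assert filter_de([r], "rnaseq_de").n_total == 1

    def test_rnaseq_requires_status_ok(self):
        r = _result(log2fc=3.0, p=0.001, q=0.001, status="FAIL")
        assert filter_de([r], "rnaseq_de").n_total == 0

    def test_cis_screen_boundary_is_strict(self):
        r = _result(log2fc=1.5, p=0.04, q=0.04)
        assert filter_de([r], "cis_screen").n_total == 0
        r2 = _result(log2fc=1.5000001, p=0.04, q=0.04)
        assert filter_de([r2], "cis_screen").n_total == 1

    def test_plot_inclusion_is_an_or_rule(self):
        only_fc = _result(log2fc=1.0, p=0.9, q=0.9)
        only_p = _result(log2fc=0.1, p=0.01, q=0.2)
        neither = _result(log2fc=0.1, p=0.9, q=0.9)
        assert filter_de([only_fc], "plot_inclusion").n_total == 1
        assert filter_de([only_p], "plot_inclusion").n_total == 1
        assert filter_de([neither], "plot_inclusion").n_total == 0

    def test_mixed_comparisons_rejected(self):
        with pytest.raises(DataError, match="mixed comparisons"):
            filter_de(
                [_result(comparison="B_vs_A"), _result(comparison="C_vs_A")],
                "rnaseq_de",
            )

    def test_survivors_partition_into_up_and_down(self):
        rs = [
            _result(log2fc=v, p=0.001, q=0.001, tid=f"t{i}")
            for i, v in enumerate([2.0, -2.0, 3.0, -1.5, 0.0])
        ]
        f = filter_de(rs, "rnaseq_de")
        assert f.n_up + f.n_down == f.n_total

    @given(st.data())
    def test_tightening_a_threshold_never_adds_survivors(self, data):
        rs = [
            _result(
                log2fc=data.draw(st.floats(-4, 4), label=f"fc{i}"),
                p=data.draw(st.floats(0, 1), label=f"p{i}"),
                q=data.draw(st.floats(0, 1), label=f"q{i}"),
                tid=f"t{i}",
            )
            for i in range(10)
        ]
        loose = PRESETS["cis_screen"]
        tight = ThresholdPreset(
            name="tight",
            min_abs_log2fc=loose.min_abs_log2fc + 0.5,
            max_p=loose.max_p / 2,
            strict_fc=True,
            strict_p=True,
        )
        kept_loose = {r.transcript_id for r in filter_de(rs, loose).retained}
        kept_tight = {r.transcript_id for r in filter_de(rs, tight).retained}
        assert kept_tight <= kept_loose

    def test_preset_needs_exactly_one_significance_criterion(self):
        with pytest.raises(DataError):
            ThresholdPreset(name="bad", min_abs_log2fc=1.0, max_p=0.05, max_q=0.05)


def _hypergeom_tail_bruteforce(m, k_set, n_draw, k_obs):
    tot = comb(m, n_draw)
    return sum(
        comb(k_set, k) * comb(m - k_set, n_draw - k)
        for k in range(k_obs, min(k_set, n_draw) + 1)
    ) / tot


class TestFisherEnrichment:
    def test_matches_exact_hypergeometric_tail(self):
        universe = {f"g{i}" for i in range(100)}
        gene_set = {f"g{i}" for i in range(10)}
        de = {f"g{i}" for i in range(8)} | {f"g{i}" for i in range(50, 62)}
        out = enrichment_fisher(de, universe, {"S": gene_set})
        assert out.loc["S", "n_overlap"] == 8
        expected = _hypergeom_tail_bruteforce(100, 10, 20, 8)
        assert out.loc["S", "p"] == pytest.approx(expected, rel=1e-10)

    @pytest.mark.parametrize("m,k_set,n_draw", [(20, 5, 8), (50, 12, 20), (10, 3, 3)])
    def test_brute_force_equivalence_on_small_universes(self, m, k_set, n_draw):
        universe = {f"g{i}" for i in range(m)}
        gene_set = {f"g{i}" for i in range(k_set)}
        de = {f"g{i}" for i in range(n_draw)}
        out = enrichment_fisher(de, universe, {"S": gene_set})
        k_obs = len(gene_set & de)
        assert out.loc["S", "p"] == pytest.approx(
            _hypergeom_tail_bruteforce(m, k_set, n_draw, k_obs), rel=1e-10
        )

    def test_zero_overlap_gives_p_one(self):
        universe = {f"g{i}" for i in range(20)}
        out = enrichment_fisher({"g0"}, universe, {"S": {"g10", "g11"}})
        assert out.loc["S", "p"] == 1.0

    def test_gene_set_equal_to_universe_gives_p_one(self):
        universe = {f"g{i}" for i in range(20)}
        out = enrichment_fisher({"g0", "g1"}, universe, {"S": universe})
        assert out.loc["S", "n_overlap"] == 2
        assert out.loc["S", "p"] == pytest.approx(1.0)

    def test_empty_universe_rejected(self):
        with pytest.raises(DataError, match="empty"):
            enrichment_fisher(set(), set(), {"S": {"a"}})


def test_de_table_round_trips_through_frame():
    rs = [_result(log2fc=1.2, p=0.01, q=0.02, tid="tx1")]
    assert frame_to_results(results_to_frame(rs)) == rs
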