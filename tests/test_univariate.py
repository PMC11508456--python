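"""Differential-abundance stage: fold changes, rank-sum test, BH, gate."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from proteomark import (
    bh_adjust,
    differential_abundance,
    log2_fold_change,
    select_univariate,
    wilcoxon_rank_sum,
)
from proteomark.errors import InputError, ParameterError

from conftest import make_matrix


# ---------------------------------------------------------------------------
# log2 fold change
# ---------------------------------------------------------------------------

class TestLog2FoldChange:
    def test_equal_means_give_zero(self):
        m = make_matrix([[3.0, 3.0, 5.0, 1.0]], ["a", "b"], ["c", "d"])
        assert log2_fold_change(m, pseudocount=0).iloc[0] == pytest.approx(0.0)

    def test_doubled_case_mean_gives_one(self):
        m = make_matrix([[4.0, 4.0, 2.0, 2.0]], ["a", "b"], ["c", "d"])
        assert log2_fold_change(m, pseudocount=0).iloc[0] == pytest.approx(1.0)

    def test_matches_explicit_loop_arithmetic(self):
        rng = np.random.default_rng(0)
        vals = rng.lognormal(size=(5, 6))
        m = make_matrix(vals, ["a", "b", "c"], ["d", "e", "f"])
        got = log2_fold_change(m, pseudocount=0.1)
        for i in range(5):
            case_mean = sum(vals[i, :3]) / 3
            ctrl_mean = sum(vals[i, 3:]) / 3
            expected = math.log2((case_mean + 0.1) / (ctrl_mean + 0.1))
            assert got.iloc[i] == pytest.approx(expected, rel=1e-12)

    def test_zero_mean_without_pseudocount_warns_and_is_infinite(self):
        m = make_matrix([[2.0, 2.0, 0.0, 0.0]], ["a", "b"], ["c", "d"])
        with pytest.warns(RuntimeWarning):
            lfc = log2_fold_change(m, pseudocount=0)
        assert np.isposinf(lfc.iloc[0])

    def test_negative_pseudocount_rejected(self):
        m = make_matrix([[1.0, 1.0, 1.0, 1.0]], ["a", "b"], ["c", "d"])
        with pytest.raises(ParameterError):
            log2_fold_change(m, pseudocount=-1)


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum
# ---------------------------------------------------------------------------

def brute_force_two_sided_p(x, y):
    """Exact two-sided rank-sum p by enumerating all group assignments."""
    pooled = list(x) + list(y)
    n1 = len(x)
    ranks = {v: r + 1 for r, v in enumerate(sorted(pooled))}
    obs = sum(ranks[v] for v in x)
    sums = [sum(ranks[pooled[i]] for i in combo)
            for combo in itertools.combinations(range(len(pooled)), n1)]
    mean = (n1 * (len(pooled) + 1)) / 2
    dev = abs(obs - mean)
    extreme = sum(1 for s in sums if abs(s - mean) >= dev - 1e-12)
    return extreme / len(sums)


def ranksum_null_tail(n1, n2, w_obs):
    """P(W <= w_obs) for the rank-sum null, by dynamic-programming count of
    size-n1 subsets of ranks 1..n1+n2 at each rank-sum value."""
    n = n1 + n2
    max_w = n1 * n
    counts = np.zeros((n1 + 1, max_w + 1), dtype=object)
    counts[0][0] = 1
    for r in range(1, n + 1):
        for k in range(min(r, n1), 0, -1):
            for w in range(max_w, r - 1, -1):
                counts[k][w] += counts[k - 1][w - r]
    total = math.comb(n, n1)
    return sum(counts[n1][w] for w in range(w_obs + 1)) / total


class TestWilcoxonRankSum:
    def test_small_complete_separation_is_exact(self):
        m = make_matrix([[1, 2, 3, 4, 5, 6]], ["a", "b", "c"], ["d", "e", "f"])
        p = wilcoxon_rank_sum(m).iloc[0]
        assert p == pytest.approx(0.1)  # 2 of the 20 assignments are as extreme
        assert p == pytest.approx(brute_force_two_sided_p([1, 2, 3], [4, 5, 6]))

    def test_study_sized_separation_matches_null_enumeration(self):
        # n = (10, 20), complete separation: two-sided p is twice the
        # minimal tail of the enumerated rank-sum null distribution
        case = list(range(1, 11))
        ctrl = list(range(11, 31))
        m = make_matrix([case + ctrl], [f"c{i}" for i in range(10)],
                        [f"h{i}" for i in range(20)])
        p = wilcoxon_rank_sum(m).iloc[0]
        min_w = 10 * 11 // 2  # ranks 1..10
        expected = 2 * ranksum_null_tail(10, 20, min_w)
        assert expected == pytest.approx(2 / math.comb(30, 10))
        assert p == pytest.approx(expected, rel=1e-9)

    def test_identical_distributions_give_p_one(self):
        m = make_matrix([[7.0] * 6], ["a", "b", "c"], ["d", "e", "f"])
        assert wilcoxon_rank_sum(m).iloc[0] == 1.0

    def test_single_sample_group_rejected(self):
        m = make_matrix([[1.0, 2.0, 3.0]], ["a"], ["b", "c"])
        with pytest.raises(InputError):
            wilcoxon_rank_sum(m)

    def test_label_swap_negates_lfc_and_keeps_p(self):
        rng = np.random.default_rng(1)
        vals = rng.lognormal(size=(8, 9))
        m1 = make_matrix(vals, ["a", "b", "c", "d"], ["e", "f", "g", "h", "i"])
        m2 = make_matrix(vals, ["e", "f", "g", "h", "i"], ["a", "b", "c", "d"])
        m2.values = m1.values  # same column order, swapped labels
        np.testing.assert_allclose(
            log2_fold_change(m1, pseudocount=0).to_numpy(),
            -log2_fold_change(m2, pseudocount=0).to_numpy(),
            atol=1e-12,
        )
        np.testing.assert_allclose(
            wilcoxon_rank_sum(m1).to_numpy(), wilcoxon_rank_sum(m2).to_numpy(), rtol=1e-12
        )


# ---------------------------------------------------------------------------
# Benjamini-Hochberg
# ---------------------------------------------------------------------------

def bh_bruteforce(pvals):
    """Step-up BH written directly from its definition."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, pvals[i] * m / rank)
        adj[i] = running
    return adj


class TestBHAdjust:
    def test_single_pvalue_unchanged(self):
        assert bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_hand_computed_stepup(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_all_ones_stay_ones(self):
        np.testing.assert_allclose(bh_adjust([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])

    def test_out_of_range_rejected(self):
        with pytest.raises(InputError):
            bh_adjust([0.5, 1.5])

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=20))
    def test_matches_bruteforce_oracle(self, pvals):
        np.testing.assert_allclose(bh_adjust(pvals), bh_bruteforce(pvals), atol=1e-12)

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=20))
    def test_adjusted_never_below_raw_max_p(self, pvals):
        adj = bh_adjust(pvals)
        assert np.all(adj <= 1.0) and np.all(adj >= 0.0)
        # monotone in the p-ordering
        order = np.argsort(pvals, kind="stable")
        assert np.all(np.diff(adj[order]) >= -1e-12)


# ---------------------------------------------------------------------------
# selection gate
# ---------------------------------------------------------------------------

class TestSelectionGate:
    @pytest.mark.parametrize(
        "log2fc,fdr,expected",
        [
            (0.40, 0.030974, True),   # moderate FC, significant FDR: in
            (0.33, 0.051262, False),  # fails both the FC and FDR gates
            (0.0, 0.0, False),        # no fold change at all
        ],
    )
    def test_fc_and_fdr_gate(self, log2fc, fdr, expected):
        results = pd.DataFrame(
            {"log2fc": [log2fc], "pvalue": [fdr], "fdr": [fdr]}, index=["X1"]
        )
        summary = select_univariate(results, fc_threshold=1.3, alpha=0.05)
        assert ("X1" in summary.selected) is expected

    def test_log2_scale_switch_raises_the_bar(self):
        results = pd.DataFrame(
            {"log2fc": [0.40], "pvalue": [0.01], "fdr": [0.01]}, index=["X1"]
        )
        assert select_univariate(results, 1.3, 0.05, fc_scale="ratio").n_selected == 1
        assert select_univariate(results, 1.3, 0.05, fc_scale="log2").n_selected == 0

    def test_subunity_threshold_rejected(self):
        results = pd.DataFrame({"log2fc": [1.0], "pvalue": [0.01], "fdr": [0.01]})
        with pytest.raises(ParameterError):
            select_univariate(results, fc_threshold=0.5)

    def test_up_down_split(self):
        results = pd.DataFrame(
            {"log2fc": [2.0, -2.0, 1.5], "pvalue": [0.001] * 3, "fdr": [0.001] * 3},
            index=["A", "B", "C"],
        )
        summary = select_univariate(results)
        assert (summary.n_up, summary.n_down) == (2, 1)


def test_differential_abundance_table_is_consistent(small_matrix):
    table = differential_abundance(small_matrix, pseudocount=0)
    assert list(table.columns) == ["log2fc", "pvalue", "fdr", "selected"]
    assert ((table["fdr"] >= table["pvalue"] - 1e-12)).all()
    gate = (table["log2fc"].abs() >= math.log2(1.3)) & (table["fdr"] < 0.05)
    assert (table["selected"] == gate).all()
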