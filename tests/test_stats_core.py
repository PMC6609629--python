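"""Elementary statistics against hand computations, brute-force enumeration
oracles and the scipy/statsmodels reference implementations."""

import math
from itertools import combinations

import numpy as np
import pytest
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from metasig.stats_core import (
    ContingencyTable2x2,
    DegenerateStatisticError,
    bh_adjust,
    correlate,
    fisher_exact_2x2,
    hypergeom_upper_tail,
    welch_t,
    wilcoxon_rank_sum,
)


def fisher_two_sided_bruteforce(a, b, c, d):
    """Independent oracle: enumerate every table with the observed margins and
    sum point probabilities <= that of the observed table."""
    row1, row2, col1 = a + b, c + d, a + c
    n = row1 + row2

    def point_prob(x):
        return (
            math.comb(col1, x)
            * math.comb(n - col1, row1 - x)
            / math.comb(n, row1)
        )

    lo, hi = max(0, col1 - row2), min(row1, col1)
    p_obs = point_prob(a)
    return sum(
        p for x in range(lo, hi + 1) if (p := point_prob(x)) <= p_obs * (1 + 1e-7)
    )


class TestFisherExact:
    @pytest.mark.parametrize(
        "table, expected, digits",
        [
            ((8, 13, 130, 63), 0.014, 3),  # age split, metastatic vs primary
            ((1, 1, 1, 172), 0.023, 3),  # lymph-node involvement
            ((5, 5, 5, 5), 1.0, 6),
            ((2, 0, 0, 2), 1 / 3, 6),
        ],
    )
    def test_two_sided_values(self, table, expected, digits):
        res = fisher_exact_2x2(ContingencyTable2x2(*table))
        assert round(res.p_value, digits) == pytest.approx(expected, abs=10 ** -digits / 2)

    def test_matches_bruteforce_enumeration_small_tables(self):
        rng = np.random.default_rng(5)
        for _ in range(60):
            n = int(rng.integers(1, 41))
            cells = rng.multinomial(n, [0.25] * 4)
            a, b, c, d = (int(x) for x in cells)
            got = fisher_exact_2x2(ContingencyTable2x2(a, b, c, d)).p_value
            want = fisher_two_sided_bruteforce(a, b, c, d)
            assert got == pytest.approx(want, rel=1e-9)

    def test_matches_scipy(self):
        rng = np.random.default_rng(6)
        for _ in range(30):
            cells = rng.integers(0, 30, size=4)
            if cells.sum() == 0:
                continue
            a, b, c, d = (int(x) for x in cells)
            got = fisher_exact_2x2(ContingencyTable2x2(a, b, c, d)).p_value
            want = sps.fisher_exact([[a, b], [c, d]]).pvalue
            assert got == pytest.approx(want, rel=1e-6)

    def test_invariant_under_row_and_column_swap(self):
        t = ContingencyTable2x2(3, 9, 14, 2)
        swapped = ContingencyTable2x2(2, 14, 9, 3)  # both rows and columns
        assert fisher_exact_2x2(t).p_value == pytest.approx(
            fisher_exact_2x2(swapped).p_value, rel=1e-12
        )

    def test_odds_ratio_and_errors(self):
        assert fisher_exact_2x2(ContingencyTable2x2(2, 1, 1, 2)).statistic == pytest.approx(4.0)
        assert math.isinf(fisher_exact_2x2(ContingencyTable2x2(2, 0, 0, 2)).statistic)
        with pytest.raises(ValueError):
            ContingencyTable2x2(-1, 1, 1, 1)


class TestWelchT:
    def test_identical_samples_t_zero(self):
        res = welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_worked_example(self):
        res = welch_t([0.9, 1.0, 1.1], [1.9, 2.0, 2.1])
        assert res.statistic == pytest.approx(-12.2474, abs=1e-4)

    def test_antisymmetric_and_matches_scipy(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(0, 1, 9), rng.normal(0.5, 2, 14)
        fwd, rev = welch_t(x, y), welch_t(y, x)
        assert fwd.statistic == pytest.approx(-rev.statistic)
        ref = sps.ttest_ind(x, y, equal_var=False)
        assert fwd.statistic == pytest.approx(ref.statistic)
        assert fwd.p_value == pytest.approx(ref.pvalue)

    def test_degenerate_zero_variance(self):
        assert welch_t([1, 1, 1], [1, 1, 1]).p_value == 1.0
        with pytest.raises(DegenerateStatisticError):
            welch_t([1, 1, 1], [2, 2, 2])


class TestWilcoxonRankSum:
    def test_exact_small_sample(self):
        # all C(4,2)=6 rank assignments; observed is one of 2 extremes
        res = wilcoxon_rank_sum([1, 2], [3, 4])
        assert res.method == "wilcoxon_exact"
        assert res.p_value == pytest.approx(2 / 6)

    def test_identical_tied_samples_approximate_p_one(self):
        x = [1.0, 1.0, 2.0] * 4
        res = wilcoxon_rank_sum(x, x)
        assert res.method == "wilcoxon_normal"
        assert res.p_value == pytest.approx(1.0)

    def test_large_shift_significant(self):
        rng = np.random.default_rng(8)
        x = rng.normal(0, 1, 50)
        y = rng.normal(2, 1, 50)
        assert wilcoxon_rank_sum(x, y).p_value < 1e-6

    def test_exact_and_normal_paths_agree(self):
        # tie-free 8x8 samples: exact enumeration vs normal approximation
        rng = np.random.default_rng(21)
        for _ in range(10):
            x = rng.normal(0, 1, 8)
            y = rng.normal(0.8, 1, 8)
            exact = wilcoxon_rank_sum(x, y, method="exact")
            approx = wilcoxon_rank_sum(x, y, method="normal")
            assert exact.method == "wilcoxon_exact"
            assert exact.p_value == pytest.approx(approx.p_value, abs=0.02)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])


class TestCorrelate:
    def test_worked_example(self):
        sp = correlate([1, 2, 3], [1, 4, 9], "spearman")
        pe = correlate([1, 2, 3], [1, 4, 9], "pearson")
        assert sp.r == pytest.approx(1.0)
        assert pe.r == pytest.approx(0.9897, abs=1e-4)

    def test_perfect_negative(self):
        x = np.arange(10.0)
        assert correlate(x, -x, "pearson").r == pytest.approx(-1.0)
        assert correlate(x, -x, "spearman").r == pytest.approx(-1.0)

    @pytest.mark.parametrize("method", ["pearson", "spearman"])
    def test_matches_scipy(self, method):
        rng = np.random.default_rng(4)
        x = rng.normal(size=25)
        y = 0.4 * x + rng.normal(size=25)
        got = correlate(x, y, method)
        ref = sps.pearsonr(x, y) if method == "pearson" else sps.spearmanr(x, y)
        assert got.r == pytest.approx(ref.statistic, rel=1e-9)
        assert got.p_value == pytest.approx(ref.pvalue, rel=1e-6)

    def test_zero_variance_flagged(self):
        with pytest.raises(DegenerateStatisticError):
            correlate([1, 1, 1], [1, 2, 3])

    def test_planted_inverse_correlation_sign(self, hotpam_study):
        # suppressor gene is generated with r=-0.6 against the driver gene
        met = hotpam_study.annotation.samples_of("metastatic")
        x = hotpam_study.expression.values.loc["DRIVER1", met]
        y = hotpam_study.expression.values.loc["SUPP1", met]
        assert correlate(x, y, "pearson").r < 0
        assert correlate(x, y, "spearman").r < 0


class TestBHAdjust:
    def test_step_up_by_hand(self):
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_single_value(self):
        assert bh_adjust([1.0]) == [1.0]

    def test_monotone_and_matches_statsmodels(self):
        rng = np.random.default_rng(9)
        p = rng.uniform(size=50)
        adj = np.array(bh_adjust(p))
        assert (adj >= p - 1e-12).all()
        ref = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(adj, ref)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestHypergeomTail:
    def test_matches_bruteforce_sum(self):
        # 5 of 10 hits in a 20-gene set, universe 1000
        def brute(k, n_draw, n_success, n_total):
            return sum(
                math.comb(n_success, x)
                * math.comb(n_total - n_success, n_draw - x)
                / math.comb(n_total, n_draw)
                for x in range(k, min(n_draw, n_success) + 1)
            )

        got = hypergeom_upper_tail(5, 10, 20, 1000)
        assert got == pytest.approx(brute(5, 10, 20, 1000), rel=1e-9)
        assert hypergeom_upper_tail(0, 10, 20, 1000) == 1.0
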