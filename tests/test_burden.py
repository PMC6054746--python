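"""Binomial burden tests, multiple-testing control, and summaries."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import bh_stepup_bruteforce, binom_upper_tail_bruteforce
from rvburden.burden import (
    GeneBurdenTable,
    GeneSet,
    attributable_fraction,
    bh_fdr,
    binomial_burden_test,
    bonferroni_threshold,
    carrier_frequency,
    gene_set_burden,
    genome_wide_scan,
    qq_data,
    synonymous_calibration,
)


def make_table(genes, x_case, x_control, n_case=144, n_control=7509, **kwargs):
    return GeneBurdenTable(
        pd.DataFrame({"gene": genes, "x_case": x_case, "x_control": x_control}),
        n_case,
        n_control,
        **kwargs,
    )


class TestBinomialBurdenTest:
    def test_sox17_regime(self):
        """5 case vs 5 control qualifying variants in 144 vs 7509 subjects."""
        r = binomial_burden_test(5, 5, 144, 7509)
        assert r.p_value == pytest.approx(5.5e-7, rel=0.01)
        assert round(r.enrichment_rate) == 52

    def test_enrichment_equals_proportion_odds(self):
        """The frequency ratio equals the odds of the binomial proportion
        estimate against the null case fraction."""
        r = binomial_burden_test(5, 5, 144, 7509)
        p_hat = 5 / 10
        rho = 144 / (144 + 7509)
        odds = (p_hat / (1 - p_hat)) / (rho / (1 - rho))
        assert r.enrichment_rate == pytest.approx(odds)

    def test_zero_case_count_gives_p_one(self):
        for k in (0, 1, 7):
            assert binomial_burden_test(0, k, 10, 100).p_value == 1.0

    def test_two_one_hand_enumeration(self):
        # X ~ Binomial(3, 0.1); p = P(X >= 2) = pmf(2) + pmf(3)
        expected = 3 * 0.1**2 * 0.9 + 0.1**3
        r = binomial_burden_test(2, 1, 10, 90)
        assert r.p_value == pytest.approx(expected)

    def test_zero_control_count_infinite_enrichment(self):
        r = binomial_burden_test(3, 0, 100, 1000)
        assert math.isinf(r.enrichment_rate)
        assert 0 < r.p_value < 1
        assert any("x_control=0" in n for n in r.notes)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            binomial_burden_test(-1, 5, 10, 10)
        with pytest.raises(ValueError):
            binomial_burden_test(5, -1, 10, 10)

    @given(
        x_case=st.integers(0, 25),
        x_control=st.integers(0, 25),
        n_case=st.integers(1, 500),
        n_control=st.integers(1, 5000),
    )
    @settings(max_examples=300, deadline=None)
    def test_matches_bruteforce_oracle_small_totals(self, x_case, x_control, n_case, n_control):
        """Closed-form upper tail equals pmf summation for all totals <= 50."""
        r = binomial_burden_test(x_case, x_control, n_case, n_control)
        rho = n_case / (n_case + n_control)
        oracle = binom_upper_tail_bruteforce(x_case, x_case + x_control, rho)
        assert r.p_value == pytest.approx(oracle, rel=1e-9, abs=1e-12)

    def test_label_swap_gives_complementary_tail_not_same_p(self):
        """Swapping cohort labels tests the other tail; the one-sided p is
        asymmetric, with P(X>=k) + P(X'>=n-k) = 1 + pmf overlap."""
        x_case, x_control, n_case, n_control = 7, 2, 50, 200
        forward = binomial_burden_test(x_case, x_control, n_case, n_control).p_value
        swapped = binomial_burden_test(x_control, x_case, n_control, n_case).p_value
        n = x_case + x_control
        rho = n_case / (n_case + n_control)
        overlap = math.comb(n, x_case) * rho**x_case * (1 - rho) ** (n - x_case)
        assert forward + swapped == pytest.approx(1 + overlap)
        assert forward != pytest.approx(swapped)


class TestBonferroni:
    def test_threshold_values(self):
        assert bonferroni_threshold(17_701, 0.05) == pytest.approx(2.8e-6, rel=0.02)
        assert bonferroni_threshold(1, 0.05) == 0.05
        assert bonferroni_threshold(10, 0.05) == 0.005

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0, 0.05)
        with pytest.raises(ValueError):
            bonferroni_threshold(10, 1.5)


class TestBhFdr:
    def test_single_p_is_itself(self):
        assert bh_fdr([0.3]) == pytest.approx([0.3])

    def test_all_equal_stay_equal(self):
        q = bh_fdr([0.02] * 5)
        assert np.allclose(q, 0.02)

    def test_hand_computed_stepup(self):
        # m*p(i)/i = [.04,.04,.04,.04]; cummin leaves all at .04
        assert bh_fdr([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])
        with pytest.raises(ValueError):
            bh_fdr([-0.1])

    @given(
        p=st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=200)
    )
    @settings(max_examples=200, deadline=None)
    def test_equals_independent_stepup_reimplementation(self, p):
        q = bh_fdr(p)
        oracle = bh_stepup_bruteforce(p)
        assert np.allclose(q, oracle)
        assert (q <= 1).all()
        order = np.argsort(p, kind="mergesort")
        assert (np.diff(q[order]) >= -1e-12).all()  # monotone in sorted-p order


class TestGenomeWideScan:
    def test_planted_gene_ranks_first(self):
        rng = np.random.default_rng(7)
        n_genes = 1000
        x_control = rng.poisson(5, n_genes)
        x_case = rng.poisson(0.1, n_genes)
        genes = [f"G{i}" for i in range(n_genes)] + ["PLANTED"]
        table = make_table(
            genes, np.append(x_case, 6), np.append(x_control, 5)
        )
        scan = genome_wide_scan(table)
        assert scan.iloc[0]["gene"] == "PLANTED"

    def test_all_zero_table(self):
        scan = genome_wide_scan(make_table(["A", "B"], [0, 0], [0, 0]))
        assert (scan["p_value"] == 1.0).all()
        assert (scan["p_bonferroni"] == 1.0).all()

    def test_n_tests_override_bonferroni(self):
        """A single-gene table adjusted across a 17,701-gene universe stays
        genome-wide significant in the 5-vs-5 regime."""
        scan = genome_wide_scan(make_table(["S"], [5], [5]), n_tests=17_701)
        assert scan.iloc[0]["p_bonferroni"] == pytest.approx(5.5e-7 * 17_701, rel=0.02)
        assert scan.iloc[0]["p_bonferroni"] < 0.05

    def test_matches_scalar_test_per_gene(self):
        rng = np.random.default_rng(0)
        genes = [f"G{i}" for i in range(50)]
        xc, xk = rng.poisson(2, 50), rng.poisson(2, 50)
        table = make_table(genes, xc, xk, n_case=100, n_control=900)
        scan = genome_wide_scan(table).set_index("gene")
        for g, a, b in zip(genes, xc, xk):
            r = binomial_burden_test(int(a), int(b), 100, 900)
            assert scan.loc[g, "p_value"] == pytest.approx(r.p_value)


class TestGeneSetBurden:
    def test_single_gene_set_equals_single_test(self):
        table = make_table(["A", "B"], [3, 1], [10, 2])
        r = gene_set_burden(table, GeneSet("one", frozenset({"A"})))
        single = binomial_burden_test(3, 10, 144, 7509)
        assert r.p_value == pytest.approx(single.p_value)
        assert r.enrichment_rate == pytest.approx(single.enrichment_rate)

    def test_pooled_ratio_round_trip(self):
        """Counts built to a 5.7x case/control frequency ratio pool back to
        an enrichment of 5.7."""
        n_case, n_control = 144, 7509
        x_control = [40, 60]  # pooled 100 -> control freq 100/7509
        target = 5.7
        pooled_case = target * 100 / n_control * n_case  # 10.93...
        # use integer-friendly construction: scale so x_case integral
        x_case = [8, 3]  # pooled 11
        table = make_table(["A", "B"], x_case, x_control)
        r = gene_set_burden(table, GeneSet("s", frozenset({"A", "B"})))
        assert r.x_case == 11 and r.x_control == 100
        assert r.enrichment_rate == pytest.approx((11 / 144) / (100 / 7509))
        assert r.enrichment_rate == pytest.approx(target, rel=0.01)
        assert pooled_case == pytest.approx(11, rel=0.01)

    def test_zero_count_set_p_one(self):
        table = make_table(["A", "B"], [0, 0], [0, 0])
        assert gene_set_burden(table, GeneSet("s", frozenset({"A", "B"}))).p_value == 1.0

    def test_missing_members_contribute_zero_and_logged(self, caplog):
        table = make_table(["A"], [2], [5])
        with caplog.at_level("INFO"):
            r = gene_set_burden(table, GeneSet("s", frozenset({"A", "NOTHERE"})))
        assert r.x_case == 2
        assert any("absent" in n for n in r.notes)

    def test_empty_effective_set_errors(self):
        table = make_table(["A"], [2], [5])
        with pytest.raises(ValueError):
            gene_set_burden(table, GeneSet("s", frozenset({"X", "Y"})))


class TestSynonymousCalibration:
    def test_matched_rates_not_flagged(self):
        """Cases and controls from identical per-gene synonymous rates give
        pooled enrichment near 1 in the vast majority of draws."""
        rng = np.random.default_rng(42)
        n_case, n_control, n_genes, rate = 144, 7509, 5000, 1.5e-3
        in_band = 0
        n_rep = 20
        for _ in range(n_rep):
            xc = rng.poisson(n_case * rate, n_genes)
            xk = rng.poisson(n_control * rate, n_genes)
            table = make_table(
                [f"G{i}" for i in range(n_genes)], xc, xk,
                variant_class_filter="rare synonymous",
            )
            report = synonymous_calibration(table)
            assert report.result.x_case >= 5e4 * 0.01  # sanity: counts pooled
            if not report.flagged:
                in_band += 1
        assert in_band >= int(0.95 * n_rep)

    def test_batch_shifted_rates_flagged(self):
        rng = np.random.default_rng(1)
        n_genes = 5000
        xc = rng.poisson(144 * 1.5e-3 * 1.3, n_genes)  # cases at 1.3x
        xk = rng.poisson(7509 * 1.5e-3, n_genes)
        table = make_table(
            [f"G{i}" for i in range(n_genes)], xc, xk,
            variant_class_filter="rare synonymous",
        )
        report = synonymous_calibration(table)
        assert report.flagged and report.status == "flagged"

    def test_zero_variants_insufficient_data(self):
        table = make_table(["A"], [0], [0], variant_class_filter="rare synonymous")
        report = synonymous_calibration(table)
        assert report.status == "insufficient data"
        assert report.result is None and not report.flagged


class TestSummaries:
    @pytest.mark.parametrize(
        "carriers,subjects,expected,digits",
        [(3, 413, 0.7, 1), (5, 7509, 0.07, 2), (16, 250, 6.4, 1)],
    )
    def test_carrier_frequency_printed_values(self, carriers, subjects, expected, digits):
        assert round(carrier_frequency(carriers, subjects), digits) == expected

    def test_carrier_frequency_errors(self):
        with pytest.raises(ValueError):
            carrier_frequency(1, 0)
        with pytest.raises(ValueError):
            carrier_frequency(5, 3)

    def test_attributable_fraction_difference_formula(self):
        value, formula = attributable_fraction(5, 144, 5, 7509)
        assert value == pytest.approx(100 * (5 / 144 - 5 / 7509))
        assert formula == "frequency_difference"

    def test_attributable_fraction_degenerate(self):
        assert attributable_fraction(0, 50, 0, 70)[0] == 0.0
        value, _ = attributable_fraction(4, 100, 0, 500)
        assert value == pytest.approx(carrier_frequency(4, 100))


class TestQQData:
    def test_single_value(self):
        qq = qq_data([0.5])
        assert qq["expected_neglog10"].iloc[0] == pytest.approx(-np.log10(0.5))
        assert qq["observed_neglog10"].iloc[0] == pytest.approx(-np.log10(0.5))

    def test_uniform_p_near_diagonal(self):
        rng = np.random.default_rng(3)
        qq = qq_data(rng.random(20_000))
        # rows are sorted by ascending p, so the noisy extreme-tail points
        # sit first; bound the bulk Kolmogorov-style
        delta = (qq["observed_neglog10"] - qq["expected_neglog10"]).iloc[50:].abs()
        assert delta.max() < 0.25

    def test_planted_signal_deviates_above(self):
        rng = np.random.default_rng(4)
        p = np.append(rng.random(999), 1e-9)
        qq = qq_data(p)
        top = qq.iloc[0]  # smallest p
        assert top["observed_neglog10"] - top["expected_neglog10"] > 4
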