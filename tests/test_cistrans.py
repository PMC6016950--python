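"""Cis/trans decomposition: filters, estimators, exact tests, classification.

Expected values for the exact tests are frozen from independent oracles:
brute-force enumeration of the Binomial(n, 1/2) mass for the allelic-balance
test, direct evaluation of 2*sum(O*ln(O/E)) for the G statistic, and full
sign-assignment enumeration for the Wilcoxon test.
"""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from regdiv import cistrans
from regdiv.cistrans import (
    binom_pvalue_balanced,
    classify_genes,
    contingency_analysis,
    estimate_cis,
    estimate_trans,
    g_statistic,
    percent_cis,
    pool_and_filter,
    test_allelic_bias as allelic_bias_test,
    test_cis as cis_family_test,
    test_trans as trans_family_test,
)


def pooled_frame(rows):
    return pd.DataFrame(
        rows, columns=["derived_reads", "ancestral_reads"],
        index=pd.Index([f"g{i}" for i in range(len(rows))], name="gene_id"),
    )


class TestPoolAndFilter:
    def test_hand_built_survivor_set(self, hand_allele_counts):
        passed, filters = pool_and_filter(hand_allele_counts)
        assert set(passed.index) == {
            "keep_balanced", "keep_skewed", "keep_boundary",
            "keep_32fold", "keep_small", "keep_big",
        }
        assert filters["low_total"] == "low_reads"
        assert filters["zero_allele"] == "zero_allele"
        assert filters["high_fold"] == "high_fold"
        assert set(filters["low_and_zero"].split(",")) == {"low_reads", "zero_allele"}

    def test_pooling_sums_replicates(self):
        table = pd.DataFrame(
            [("g", "r1", 30, 10), ("g", "r2", 20, 15)],
            columns=["gene_id", "replicate", "derived_count", "ancestral_count"],
        )
        passed, _ = pool_and_filter(table)
        assert passed.loc["g", "derived_reads"] == 50
        assert passed.loc["g", "ancestral_reads"] == 25

    def test_min_reads_zero_removes_nothing_when_alleles_positive(self):
        table = pd.DataFrame(
            [("a", "r1", 3, 2), ("b", "r1", 1, 1)],
            columns=["gene_id", "replicate", "derived_count", "ancestral_count"],
        )
        passed, filters = pool_and_filter(table, min_reads=0)
        assert len(passed) == 2 and len(filters) == 0


class TestEstimators:
    @pytest.mark.parametrize(
        "d,a,expected", [(100, 100, 0.0), (80, 20, 2.0), (20, 80, -2.0)]
    )
    def test_cis_known_values(self, d, a, expected):
        assert estimate_cis(pooled_frame([(d, a)])).iloc[0] == pytest.approx(expected)

    def test_cis_zero_count_is_contract_violation(self):
        with pytest.raises(ValueError):
            estimate_cis(pooled_frame([(10, 0)]))

    @pytest.mark.parametrize(
        "parental,cis,expected", [(2.0, 2.0, 0.0), (1.0, -1.0, 2.0), (0.0, 1.5, -1.5)]
    )
    def test_trans_is_difference(self, parental, cis, expected):
        assert estimate_trans(parental, cis) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "c,t,expected", [(1.0, 0.0, 1.0), (1.0, 1.0, 0.5), (-1.0, 3.0, 0.25)]
    )
    def test_percent_cis_known_values(self, c, t, expected):
        assert percent_cis(c, t) == pytest.approx(expected)

    def test_percent_cis_undefined_when_both_zero(self):
        assert np.isnan(percent_cis(0.0, 0.0))

    @settings(derandomize=True, max_examples=100)
    @given(st.floats(-5, 5), st.floats(-5, 5))
    def test_percent_cis_bounded(self, c, t):
        p = percent_cis(c, t)
        assert np.isnan(p) or 0.0 <= p <= 1.0

    @settings(derandomize=True, max_examples=50)
    @given(st.integers(1, 10**6), st.integers(1, 10**6), st.integers(1, 1000))
    def test_cis_estimate_scale_free(self, d, a, k):
        one = estimate_cis(pooled_frame([(d, a)])).iloc[0]
        scaled = estimate_cis(pooled_frame([(d * k, a * k)])).iloc[0]
        assert one == pytest.approx(scaled, abs=1e-12)


class TestBinomialTest:
    def test_exact_balance_is_certain(self):
        assert binom_pvalue_balanced(50, 100) == pytest.approx(1.0)

    def test_fifteen_of_twenty_oracle_value(self):
        # frozen from enumeration of the Binomial(20, 1/2) pmf (minimum-
        # likelihood two-sided rule)
        assert float(binom_pvalue_balanced(15, 20)) == pytest.approx(
            0.04138946533203125, abs=1e-12
        )

    def test_matches_enumeration_for_moderate_n(self):
        rng = np.random.default_rng(0)
        for n in [1, 2, 5, 17, 64, 201, 999, 2000]:
            ks = np.unique(rng.integers(0, n + 1, size=5))
            pmf = stats.binom.pmf(np.arange(n + 1), n, 0.5)
            for k in ks:
                enum = pmf[pmf <= pmf[k] * (1 + 1e-10)].sum()
                assert float(binom_pvalue_balanced(k, n)) == pytest.approx(
                    min(1.0, enum), abs=1e-12
                )

    def test_matches_scipy_binomtest(self):
        for n, k in [(20, 15), (33, 10), (101, 60), (512, 300)]:
            assert float(binom_pvalue_balanced(k, n)) == pytest.approx(
                stats.binomtest(k, n, 0.5).pvalue, rel=1e-10
            )

    def test_bh_qvalues_monotone_in_p_rank(self):
        pooled = pooled_frame([(60, 40), (80, 20), (55, 45), (50, 50)])
        res = cis_family_test(pooled)
        ordered = res.sort_values("p_cis")
        assert ordered["q_cis"].is_monotonic_increasing


class TestGTest:
    def test_zero_when_observed_matches_expected(self):
        parental = pooled_frame([(50, 50)])
        f = pd.Series([0.5], index=parental.index)
        res = trans_family_test(parental, cis_fraction=f, mode="fixed-cis")
        assert res["g_trans"].iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert res["p_trans"].iloc[0] == pytest.approx(1.0)

    def test_ninety_ten_oracle_value(self):
        # frozen from direct evaluation: 2*(90*ln(90/50) + 10*ln(10/50))
        parental = pooled_frame([(90, 10)])
        f = pd.Series([0.5], index=parental.index)
        res = trans_family_test(parental, cis_fraction=f, mode="fixed-cis")
        assert res["g_trans"].iloc[0] == pytest.approx(73.61284143369943, abs=1e-9)

    @settings(derandomize=True, max_examples=100)
    @given(st.integers(1, 10**5), st.integers(1, 10**5), st.floats(0.01, 0.99))
    def test_g_nonnegative(self, d, a, f):
        parental = pooled_frame([(d, a)])
        res = trans_family_test(parental, cis_fraction=pd.Series([f], index=parental.index),
                         mode="fixed-cis")
        assert res["g_trans"].iloc[0] >= -1e-9

    def test_independence_mode_matches_scipy_loglik_chi2(self):
        parental = pooled_frame([(120, 80), (30, 300)])
        hybrid = pooled_frame([(100, 90), (45, 250)])
        res = trans_family_test(parental, hybrid_pooled=hybrid, mode="independence")
        for i in range(2):
            table = [
                [hybrid.iloc[i, 0], hybrid.iloc[i, 1]],
                [parental.iloc[i, 0], parental.iloc[i, 1]],
            ]
            ref = stats.chi2_contingency(table, correction=False, lambda_="log-likelihood")
            assert res["g_trans"].iloc[i] == pytest.approx(ref.statistic, rel=1e-9)
            assert res["p_trans"].iloc[i] == pytest.approx(ref.pvalue, rel=1e-9)

    def test_fixed_cis_boundary_fraction_rejected(self):
        parental = pooled_frame([(10, 10)])
        with pytest.raises(ValueError):
            trans_family_test(parental, cis_fraction=pd.Series([1.0], index=parental.index),
                       mode="fixed-cis")


class TestAllelicBias:
    def test_small_vector_matches_sign_enumeration(self):
        x = np.array([-3.0, -1.0, 2.0, 4.0])
        # oracle: enumerate all 2^4 sign assignments of the rank sum
        ranks = stats.rankdata(np.abs(x))
        dist = np.array(
            [sum(r for s, r in zip(signs, ranks) if s)
             for signs in itertools.product([0, 1], repeat=len(x))]
        )
        w = ranks[x > 0].sum()
        expected = min(1.0, 2 * min((dist <= w).mean(), (dist >= w).mean()))
        _, p = allelic_bias_test(pd.Series(x))
        assert p == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.875)

    def test_all_positive_vector_extreme_tail(self):
        _, p = allelic_bias_test(pd.Series([1.0, 2.0, 3.0, 4.0]))
        assert p == pytest.approx(2 / 16)  # both one-sided extremes of 2^4

    def test_negation_invariance(self):
        x = pd.Series([-2.0, 0.5, 1.5, -0.3, 0.9])
        _, p1 = allelic_bias_test(x)
        _, p2 = allelic_bias_test(-x)
        assert p1 == pytest.approx(p2, rel=1e-12)

    def test_zeros_dropped_before_ranking(self):
        x = pd.Series([0.0, 0.0, 1.0, 2.0, -3.0])
        _, p1 = allelic_bias_test(x)
        _, p2 = allelic_bias_test(pd.Series([1.0, 2.0, -3.0]))
        assert p1 == pytest.approx(p2)

    def test_all_zero_undefined_with_warning(self):
        with pytest.warns(UserWarning):
            stat, p = allelic_bias_test(pd.Series([0.0, 0.0]))
        assert np.isnan(p)


class TestClassification:
    def idx(self, n):
        return pd.Index([f"g{i}" for i in range(n)])

    def test_category_assignment_rules(self):
        q_cis = pd.Series([0.001, 0.5, 0.005, 0.005, 0.5], index=self.idx(5))
        q_trans = pd.Series([0.5, 0.001, 0.005, 0.005, 0.5], index=self.idx(5))
        lc = pd.Series([1.0, 0.1, 1.0, 1.0, 0.1], index=self.idx(5))
        lt = pd.Series([0.1, 1.0, 1.0, -1.0, 0.1], index=self.idx(5))
        cats = classify_genes(q_cis, q_trans, lc, lt)
        assert cats.tolist() == [
            "cis_only", "trans_only", "concordant", "discordant", "conserved"
        ]

    def test_partition_covers_all_tested_genes(self, small_cross):
        table = small_cross["result"].table
        tested = table[table["category"].notna()]
        assert tested["category"].isin(cistrans.CATEGORIES).all()
        assert len(tested) == small_cross["result"].n_tested


class TestContingency:
    def make_table(self, cis_major_conc, cis_major_disc, trans_major_conc, trans_major_disc):
        rows = []
        spec_rows = [
            (0.9, True, cis_major_conc), (0.9, False, cis_major_disc),
            (0.1, True, trans_major_conc), (0.1, False, trans_major_disc),
        ]
        i = 0
        for pct, conc, count in spec_rows:
            for _ in range(count):
                sign_t = 1.0 if conc else -1.0
                rows.append((f"g{i}", 1.0, sign_t, pct))
                i += 1
        df = pd.DataFrame(rows, columns=["gene_id", "log2_cis", "log2_trans", "percent_cis"])
        df = df.set_index("gene_id")
        df["category"] = pd.Categorical(
            ["concordant"] * len(df), categories=list(cistrans.CATEGORIES)
        )
        return df

    def test_symmetric_table_is_uninformative(self):
        res = contingency_analysis(self.make_table(10, 10, 10, 10))
        assert res.table.to_numpy().tolist() == [[10, 10], [10, 10]]
        assert all(p == pytest.approx(1.0) for p in res.binomial_p)
        assert res.rows_comparison_p == pytest.approx(1.0)

    def test_extreme_row_closed_form_tail(self):
        res = contingency_analysis(self.make_table(0, 40, 20, 20))
        assert res.binomial_p["cis_major"] == pytest.approx(2 * 0.5**40, rel=1e-9)

    def test_row_proportions_sum_to_one(self):
        res = contingency_analysis(self.make_table(7, 13, 22, 8))
        assert np.allclose(res.row_proportions.sum(axis=1), 1.0)

    def test_empty_row_reported_untestable(self):
        res = contingency_analysis(self.make_table(0, 0, 5, 5))
        assert np.isnan(res.binomial_p["cis_major"])


class TestRegulatoryResult:
    def test_additivity_exact_for_every_tested_gene(self, small_cross):
        t = small_cross["result"].tested
        residual = (t["log2_cis"] + t["log2_trans"] - t["log2_parental"]).abs()
        assert residual.max() < 1e-12

    def test_uninformative_genes_flagged(self, small_cross):
        table = small_cross["result"].table
        truth = small_cross["truth"]
        uninformative = truth.index[~truth["informative"]]
        flagged = table.loc[table.index.intersection(uninformative), "filters_failed"]
        assert (flagged == "no_informative_variant").all()

    def test_category_counts_partition_tested_genes(self, small_cross):
        res = small_cross["result"]
        assert int(res.category_counts().sum()) == res.n_tested
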