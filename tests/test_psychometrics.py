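"""Scoring, classification, reliability and the descriptive statistics,
each checked against closed-form or brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from svamech.psychometrics import (
    DEFAULT_SCALES,
    ScaleDefinition,
    chi_square_2x2,
    classify_addiction,
    cronbach_alpha,
    harman_single_factor,
    pearson_corr_matrix,
    pooled_t_test,
    score_cohort,
    score_scale,
)

SVA = DEFAULT_SCALES["SVA"]
BV = DEFAULT_SCALES["BV"]


def _item_frame(values, items):
    return pd.DataFrame({c: v for c, v in zip(items, np.atleast_2d(values).T)})


class TestScoring:
    @pytest.mark.parametrize("fill,expected", [(1, 10), (6, 60)])
    def test_sva_total_spans_scale_range(self, fill, expected):
        df = _item_frame(np.full((1, 10), fill), SVA.items)
        assert score_scale(df, SVA)["SVA"].iloc[0] == expected

    def test_bullying_total_is_sum_of_subdimensions(self, cohort_small):
        table, _ = cohort_small
        scored = score_scale(table, BV)
        np.testing.assert_array_equal(
            scored["BV"], scored["VB"] + scored["PB"] + scored["RB"]
        )

    def test_missing_item_excludes_subject_listwise(self):
        vals = np.full((3, 10), 2.0)
        df = _item_frame(vals, SVA.items)
        df.loc[1, SVA.items[4]] = np.nan
        out = score_scale(df, SVA)
        assert out["SVA"].iloc[0] == 20 and np.isnan(out["SVA"].iloc[1])

    def test_unknown_item_column_is_schema_error(self):
        df = _item_frame(np.full((2, 4), 1), ["vb_item01", "x", "y", "z"])
        with pytest.raises(KeyError):
            score_scale(df, BV)

    def test_out_of_range_response_rejected(self):
        df = _item_frame(np.full((1, 10), 7), SVA.items)
        with pytest.raises(ValueError, match="outside"):
            score_scale(df, SVA)

    def test_subscale_definition_must_nest_in_scale(self):
        with pytest.raises(ValueError, match="not in scale"):
            ScaleDefinition("S", ("a", "b"), subscales={"sub": ("a", "q")})


class TestAddictionCutoff:
    @pytest.mark.parametrize("score,gender,expected", [
        (33, "F", "addicted"),
        (31, "F", "nonaddicted"),   # female cutoff is 33
        (31, "M", "addicted"),      # male cutoff is 31
        (30, "M", "nonaddicted"),
    ])
    def test_gender_specific_inclusive_cutoff(self, score, gender, expected):
        assert classify_addiction(score, gender) == expected

    def test_unknown_gender_rejected(self):
        with pytest.raises(ValueError, match="gender"):
            classify_addiction(35, "X")


class TestCronbachAlpha:
    def test_duplicated_items_give_alpha_one(self):
        col = np.random.default_rng(0).integers(1, 7, 50).astype(float)
        x = np.column_stack([col] * 5)
        assert cronbach_alpha(x) == pytest.approx(1.0)

    def test_independent_items_give_alpha_near_zero(self):
        x = np.random.default_rng(1).integers(1, 7, size=(2000, 10)).astype(float)
        assert abs(cronbach_alpha(x)) < 0.1

    def test_two_item_population_alpha_two_thirds(self):
        # population covariance [[1,.5],[.5,1]] -> alpha = 2*(1 - 2/3) = 2/3;
        # enforce the population moments exactly in the sample
        rng = np.random.default_rng(2)
        z = rng.standard_normal((500, 2))
        z -= z.mean(axis=0)
        # whiten empirically, then color with the target covariance
        white = z @ np.linalg.inv(np.linalg.cholesky(np.cov(z, rowvar=False))).T
        x = white @ np.linalg.cholesky([[1, 0.5], [0.5, 1]]).T
        assert cronbach_alpha(x) == pytest.approx(2 / 3, abs=1e-10)

    def test_alpha_invariant_to_item_order_and_grows_with_parallel_item(self):
        rng = np.random.default_rng(3)
        common = rng.standard_normal(800)
        items = np.column_stack(
            [0.7 * common + 0.7 * rng.standard_normal(800) for _ in range(6)]
        )
        a6 = cronbach_alpha(items)
        assert cronbach_alpha(items[:, ::-1]) == pytest.approx(a6)
        extra = 0.7 * common + 0.7 * rng.standard_normal(800)
        assert cronbach_alpha(np.column_stack([items, extra])) > a6

    def test_zero_total_variance_signalled(self):
        with pytest.raises(ValueError, match="variance"):
            cronbach_alpha(np.ones((10, 3)))


class TestHarmanSingleFactor:
    def test_independent_items_first_factor_near_uniform_share(self):
        p = 20
        x = np.random.default_rng(4).standard_normal((20000, p))
        n_factors, pct = harman_single_factor(x)
        assert pct == pytest.approx(100 / p, abs=1.5)
        assert n_factors >= p // 3  # many eigenvalues hover around 1

    def test_single_common_factor_flags_bias(self):
        # compound-symmetric corr with loading 0.9: lambda1 = 1 + 19*0.81,
        # first-factor share ~ 81.95% > 40%
        rng = np.random.default_rng(5)
        f = rng.standard_normal(20000)
        x = 0.9 * f[:, None] + np.sqrt(1 - 0.81) * rng.standard_normal((20000, 20))
        n_factors, pct = harman_single_factor(x)
        assert n_factors == 1
        assert pct == pytest.approx(100 * (1 + 19 * 0.81) / 20, abs=1.0)

    def test_invariant_to_item_permutation(self, cohort_small):
        table, _ = cohort_small
        items = table.filter(regex="_item")
        out = harman_single_factor(items)
        shuffled = items[list(items.columns[::-1])]
        out2 = harman_single_factor(shuffled)
        assert out[0] == out2[0] and out[1] == pytest.approx(out2[1])


class TestGroupStatistics:
    def test_identical_summaries_give_t_zero(self):
        t, df, p = pooled_t_test(10, 2, 50, 10, 2, 60)
        assert t == 0 and df == 108 and p == pytest.approx(1.0)

    def test_pooled_t_matches_raw_data_t(self):
        rng = np.random.default_rng(6)
        g1, g2 = rng.normal(0, 1, 40), rng.normal(0.5, 1.2, 55)
        t_raw, p_raw = stats.ttest_ind(g1, g2, equal_var=True)
        t, df, p = pooled_t_test(g1.mean(), g1.std(ddof=1), 40,
                                 g2.mean(), g2.std(ddof=1), 55)
        assert t == pytest.approx(t_raw, abs=1e-10)
        assert p == pytest.approx(p_raw, abs=1e-10)

    def test_chi_square_matches_expected_count_oracle(self):
        counts = [[13, 29], [41, 7]]
        obs = np.array(counts, float)
        exp = np.outer(obs.sum(1), obs.sum(0)) / obs.sum()
        oracle = ((obs - exp) ** 2 / exp).sum()
        chi2, df, _ = chi_square_2x2(counts)
        assert chi2 == pytest.approx(oracle, abs=1e-9) and df == 1

    def test_chi_square_uniform_table_is_zero(self):
        assert chi_square_2x2([[10, 10], [10, 10]])[0] == 0

    @given(st.lists(st.integers(1, 500), min_size=4, max_size=4))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_chi_square_invariant_to_row_and_column_swap(self, cells):
        a, b, c, d = cells
        base = chi_square_2x2([[a, b], [c, d]])[0]
        assert chi_square_2x2([[c, d], [a, b]])[0] == pytest.approx(base)
        assert chi_square_2x2([[b, a], [d, c]])[0] == pytest.approx(base)

    def test_zero_marginal_signalled(self):
        with pytest.raises(ValueError, match="marginal"):
            chi_square_2x2([[0, 0], [5, 3]])


class TestCorrelationTable:
    def test_self_and_negated_correlations(self):
        df = pd.DataFrame({"x": [1.0, 2, 3, 5], "y": [-1.0, -2, -3, -5]})
        r, _ = pearson_corr_matrix(df, ["x", "y"])
        assert r.loc["x", "x"] == pytest.approx(1)
        assert r.loc["x", "y"] == pytest.approx(-1)

    def test_observed_correlation_attenuated_by_reliability(self, cohort_large):
        # r_obs ~ r_latent * sqrt(rel_BV * rel_NA); reliabilities estimated by
        # Cronbach's alpha on the generated items
        table, truth = cohort_large
        scored = score_cohort(table)
        p = truth["params"]
        rel_bv = cronbach_alpha(table[list(DEFAULT_SCALES["BV"].items)])
        rel_na = cronbach_alpha(table[list(DEFAULT_SCALES["NA"].items)])
        expected = p.a_true * np.sqrt(rel_bv * rel_na)
        r, _ = pearson_corr_matrix(scored, ["BV", "NA"])
        assert r.loc["BV", "NA"] == pytest.approx(expected, abs=0.03)

    def test_constant_variable_signalled(self):
        df = pd.DataFrame({"x": [1.0, 2, 3], "c": [4.0, 4, 4]})
        with pytest.raises(ValueError, match="constant"):
            pearson_corr_matrix(df, ["x", "c"])


class TestScoredCohort:
    def test_totals_bounded_by_item_counts(self, scored_small):
        assert scored_small["SVA"].between(10, 60).all()
        assert scored_small["BV"].between(12, 72).all()

    def test_addiction_class_respects_gender_cutoffs(self, scored_small):
        addicted = scored_small["addiction_class"] == "addicted"
        females = scored_small["gender"] == "F"
        assert (scored_small.loc[addicted & females, "SVA"] >= 33).all()
        assert (scored_small.loc[addicted & ~females, "SVA"] >= 31).all()
        assert (scored_small.loc[~addicted & females, "SVA"] < 33).all()
        assert (scored_small.loc[~addicted & ~females, "SVA"] < 31).all()
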