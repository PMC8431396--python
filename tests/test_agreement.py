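"""ICC, weighted kappa, concordance and paired-difference statistics."""

import numpy as np
import pandas as pd
import pytest

from pdl1score.agreement import (cutoff_concordance, icc, icc_interpretation,
                                 kappa_interpretation, mean_pairwise_kappa,
                                 paired_difference, ratings_matrix,
                                 weighted_kappa)
from pdl1score.synthetic import generate_rater_scores


def icc21_oracle(x: np.ndarray) -> float:
    """ICC(2,1) recomputed from raw sum-of-squares definitions."""
    x = np.asarray(x, float)
    n, k = x.shape
    grand = x.mean()
    ss_rows = sum(k * (x[i].mean() - grand) ** 2 for i in range(n))
    ss_cols = sum(n * (x[:, j].mean() - grand) ** 2 for j in range(k))
    ss_total = ((x - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + (k / n) * (msc - mse))


class TestICC:
    def test_identical_raters_differing_cases(self):
        x = np.tile(np.arange(1.0, 7.0)[:, None], (1, 3))
        res = icc(x)
        assert res.estimate == pytest.approx(1.0)
        assert res.interpretation == "excellent"

    def test_matches_anova_oracle_on_random_matrices(self):
        rng = np.random.default_rng(41)
        for _ in range(100):
            n = int(rng.integers(4, 20))
            k = int(rng.integers(2, 6))
            x = rng.normal(rng.normal(size=(n, 1)), 1.0, (n, k))
            assert icc(x).estimate == pytest.approx(icc21_oracle(x), abs=1e-10)

    def test_integer_matrix_against_oracle(self):
        x = np.array([[9, 2, 5], [6, 1, 3], [8, 4, 6],
                      [7, 1, 2], [10, 5, 6], [6, 2, 4]], float)
        assert icc(x).estimate == pytest.approx(icc21_oracle(x), abs=1e-10)

    def test_cross_check_against_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(43)
        x = rng.normal(rng.normal(size=(12, 1)), 1.0, (12, 4))
        df = pd.DataFrame(x, columns=list("ABCD")).reset_index().melt(
            id_vars="index", var_name="rater", value_name="score")
        ref = pg.intraclass_corr(df, targets="index", raters="rater",
                                 ratings="score")
        ci_col = "CI95%" if "CI95%" in ref.columns else "CI95"
        row = ref[ref["Type"].isin(["ICC2", "ICC(A,1)"])].iloc[0]
        res = icc(x)
        assert res.estimate == pytest.approx(row["ICC"], abs=1e-9)
        assert res.ci_low == pytest.approx(row[ci_col][0], abs=0.01)
        assert res.ci_high == pytest.approx(row[ci_col][1], abs=0.01)

    def test_interpretation_bands(self):
        assert icc_interpretation(0.84) == "good"
        assert icc_interpretation(0.3) == "poor"
        assert icc_interpretation(0.5) == "moderate"
        assert icc_interpretation(0.75) == "good"
        assert icc_interpretation(0.9) == "excellent"

    def test_ci_brackets_estimate(self):
        rng = np.random.default_rng(44)
        x = rng.normal(rng.normal(size=(15, 1)) * 3, 1.0, (15, 4))
        res = icc(x)
        assert res.ci_low <= res.estimate <= res.ci_high
        assert res.p_value < 0.05

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError, match="undefined"):
            icc(np.full((5, 3), 2.0))

    def test_monotone_degradation_with_rater_noise(self):
        truth = np.linspace(0, 95, 20)
        estimates = []
        for sd in (0.0, 1.0, 5.0, 20.0):
            ratings = generate_rater_scores(truth, n_raters=4, noise_sd=sd, seed=77)
            estimates.append(icc(ratings).estimate)
        assert estimates[0] == pytest.approx(1.0)
        assert all(a > b for a, b in zip(estimates, estimates[1:]))


class TestWeightedKappa:
    def test_perfect_agreement(self):
        r = ["a", "b", "c", "a", "b"]
        assert weighted_kappa(r, r, ["a", "b", "c"]).estimate == pytest.approx(1.0)

    def test_independence_table_is_zero(self):
        r1 = ["x"] * 25 + ["x"] * 25 + ["y"] * 25 + ["y"] * 25
        r2 = ["x"] * 25 + ["y"] * 25 + ["x"] * 25 + ["y"] * 25
        assert weighted_kappa(r1, r2, ["x", "y"]).estimate == pytest.approx(0.0)

    def test_antidiagonal_table_is_minus_one(self):
        r1 = ["x"] * 50 + ["y"] * 50
        r2 = ["y"] * 50 + ["x"] * 50
        assert weighted_kappa(r1, r2, ["x", "y"]).estimate == pytest.approx(-1.0)

    def test_two_categories_reduce_to_cohen_kappa(self):
        from sklearn.metrics import cohen_kappa_score
        rng = np.random.default_rng(47)
        r1 = rng.integers(0, 2, 60)
        r2 = rng.integers(0, 2, 60)
        ours = weighted_kappa(r1, r2, [0, 1]).estimate
        assert ours == pytest.approx(cohen_kappa_score(r1, r2), abs=1e-12)

    def test_linear_weights_match_reference_on_ordinal_data(self):
        from sklearn.metrics import cohen_kappa_score
        rng = np.random.default_rng(48)
        r1 = rng.integers(0, 3, 80)
        r2 = np.clip(r1 + rng.integers(-1, 2, 80), 0, 2)
        ours = weighted_kappa(r1, r2, [0, 1, 2]).estimate
        ref = cohen_kappa_score(r1, r2, weights="linear")
        assert ours == pytest.approx(ref, abs=1e-12)

    def test_symmetry(self):
        rng = np.random.default_rng(49)
        r1 = rng.integers(0, 3, 50)
        r2 = rng.integers(0, 3, 50)
        assert (weighted_kappa(r1, r2, [0, 1, 2]).estimate
                == pytest.approx(weighted_kappa(r2, r1, [0, 1, 2]).estimate))

    def test_unknown_category_raises(self):
        with pytest.raises(ValueError, match="category"):
            weighted_kappa(["a", "z"], ["a", "a"], ["a", "b"])

    def test_interpretation_bands(self):
        assert kappa_interpretation(-0.1) == "poor"
        assert kappa_interpretation(0.1) == "mild"
        assert kappa_interpretation(0.5) == "moderate"
        assert kappa_interpretation(0.7) == "substantial"
        assert kappa_interpretation(0.85) == "near perfect"


class TestMeanPairwiseKappa:
    def test_two_raters_equal_single_pair(self):
        rng = np.random.default_rng(51)
        df = pd.DataFrame({"r1": rng.integers(0, 3, 40),
                           "r2": rng.integers(0, 3, 40)})
        mp = mean_pairwise_kappa(df, [0, 1, 2])
        wk = weighted_kappa(df["r1"], df["r2"], [0, 1, 2])
        assert mp.estimate == pytest.approx(wk.estimate)

    def test_all_raters_identical(self):
        df = pd.DataFrame({c: [0, 1, 2, 1, 0] for c in "abcd"})
        assert mean_pairwise_kappa(df, [0, 1, 2]).estimate == pytest.approx(1.0)

    def test_symmetric_duplicate_raters(self):
        rng = np.random.default_rng(52)
        a = rng.integers(0, 3, 60)
        b = rng.integers(0, 3, 60)
        df = pd.DataFrame({"r1": a, "r2": a, "r3": b})
        res = mean_pairwise_kappa(df, [0, 1, 2])
        pairs = res.method["pairs"]
        assert pairs["r1|r2"] == pytest.approx(1.0)
        assert pairs["r1|r3"] == pytest.approx(pairs["r2|r3"])
        expected = np.mean([1.0, pairs["r1|r3"], pairs["r2|r3"]])
        assert res.estimate == pytest.approx(expected)

    def test_single_rater_raises(self):
        with pytest.raises(ValueError):
            mean_pairwise_kappa(pd.DataFrame({"r1": [0, 1]}), [0, 1])


class TestCutoffConcordance:
    def test_equal_scores_fully_concordant(self):
        a = [0.5, 30, 60]
        pct, _, _ = cutoff_concordance(a, a, (1, 50))
        assert pct == 100.0

    def test_hand_mapped_example(self):
        pct, ca, cb = cutoff_concordance((0.5, 30, 60), (0.5, 0.5, 60), (1, 50))
        assert ca.tolist() == [0, 1, 2]
        assert cb.tolist() == [0, 0, 2]
        assert pct == pytest.approx(100 * 2 / 3)

    def test_single_cutoff_same_side(self):
        pct, _, _ = cutoff_concordance((2, 3, 4), (5, 6, 7), (1,))
        assert pct == 100.0

    def test_unsorted_cutoffs_raise(self):
        with pytest.raises(ValueError):
            cutoff_concordance([1], [1], (50, 1))


class TestPairedDifference:
    def test_identical_vectors_no_difference(self):
        a = np.arange(10.0)
        res = paired_difference(a, a)
        assert res["wilcoxon_p"] == 1.0
        assert res["note"] == "no difference"

    def test_exact_signed_rank_p_for_six_positive_differences(self):
        a = np.array([1, 2, 3, 4, 5, 6], float)
        b = np.zeros(6)
        res = paired_difference(a + b, b)
        assert res["wilcoxon_p"] == pytest.approx(0.03125)

    def test_statistic_invariant_under_common_shift(self):
        rng = np.random.default_rng(53)
        a = rng.normal(0, 1, 12)
        b = rng.normal(0, 1, 12)
        r1 = paired_difference(a, b)
        r2 = paired_difference(a + 100, b + 100)
        assert r1["wilcoxon_statistic"] == pytest.approx(r2["wilcoxon_statistic"])
        assert r1["wilcoxon_p"] == pytest.approx(r2["wilcoxon_p"])

    def test_shapiro_reported(self):
        rng = np.random.default_rng(54)
        res = paired_difference(rng.normal(0, 1, 20), rng.normal(0, 1, 20))
        assert 0 <= res["shapiro_p"] <= 1
        assert 0 < res["shapiro_w"] <= 1


class TestRatingsMatrix:
    def test_drops_incomplete_cases_with_count(self):
        df = pd.DataFrame({"r1": [1, 2, np.nan, 4], "r2": [1, 2, 3, 4]})
        out = ratings_matrix(df)
        assert len(out) == 3
        assert out.attrs["n_dropped"] == 1

    def test_too_few_raters_raises(self):
        with pytest.raises(ValueError):
            ratings_matrix(pd.DataFrame({"r1": [1, 2, 3]}))
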