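"""Grading, ICC, ROC, correlation and the synthetic cohort generator."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sonoac.clinstats import (
    COHORT_MARGINALS,
    GradeCutoffs,
    PDFF_CUTOFFS,
    QUS_AC_CUTOFFS,
    RatingTable,
    correlation_regression,
    grade_from_measure,
    grade_from_pdff,
    icc_two_way_random,
    operating_point_metrics,
    roc_analysis,
    synth_cohort,
)
from sonoac.errors import ConfigurationError, DegenerateInputError, InputError


class TestGrading:
    @pytest.mark.parametrize("pdff,grade", [
        (31.59, 3),   # severe steatosis example value
        (11.16, 1),   # cohort mean PDFF
        (4.9, 0),
        (5.0, 1),     # boundary inclusive
        (16.3, 2),
        (21.6, 3),
    ])
    def test_pdff_grades(self, pdff, grade):
        assert grade_from_pdff(pdff) == grade

    @pytest.mark.parametrize("ac,grade", [
        (0.65, 3),    # severe steatosis example value
        (0.36, 1),    # boundary inclusive
        (0.30, 0),
        (0.46, 2),
        (0.53, 3),
    ])
    def test_qus_ac_grades(self, ac, grade):
        assert grade_from_measure(ac, QUS_AC_CUTOFFS) == grade

    def test_negative_pdff_rejected(self):
        with pytest.raises(InputError):
            grade_from_pdff(-1.0)

    def test_unordered_cutoffs_rejected(self):
        with pytest.raises(ConfigurationError):
            GradeCutoffs("bad", (0.5, 0.4, 0.6))

    @given(st.floats(-10, 100), st.floats(-10, 100))
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_measurement(self, a, b):
        lo, hi = min(a, b), max(a, b)
        for cut in (PDFF_CUTOFFS, QUS_AC_CUTOFFS):
            assert grade_from_measure(lo, cut) <= grade_from_measure(hi, cut)


def icc_mean_squares_oracle(x: np.ndarray):
    """Independent spreadsheet-style two-way ANOVA decomposition."""
    n, k = x.shape
    grand = x.mean()
    msr = k * ((x.mean(1) - grand) ** 2).sum() / (n - 1)
    msc = n * ((x.mean(0) - grand) ** 2).sum() / (k - 1)
    sse = ((x - x.mean(1)[:, None] - x.mean(0)[None, :] + grand) ** 2).sum()
    mse = sse / ((n - 1) * (k - 1))
    single = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    mean_r = (msr - mse) / (msr + (msc - mse) / n)
    return single, mean_r


class TestICC:
    def test_identical_raters_perfect_agreement(self):
        t = RatingTable(np.array([[1.0, 1.0], [2.0, 2.0], [5.0, 5.0]]))
        res = icc_two_way_random(t)
        assert res["icc_single"] == pytest.approx(1.0)
        assert res["icc_mean"] == pytest.approx(1.0)

    def test_four_by_two_example_matches_oracle(self):
        x = np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0], [7.0, 8.0]])
        res = icc_two_way_random(RatingTable(x))
        single, mean_r = icc_mean_squares_oracle(x)
        assert res["icc_single"] == pytest.approx(single, abs=1e-12)
        assert res["icc_mean"] == pytest.approx(mean_r, abs=1e-12)

    @pytest.mark.parametrize("seed", range(8))
    def test_random_tables_match_oracle(self, seed):
        r = np.random.default_rng(seed)
        n, k = int(r.integers(4, 21)), int(r.integers(2, 5))
        x = r.standard_normal((n, k)) + r.standard_normal((n, 1))
        res = icc_two_way_random(RatingTable(x))
        single, mean_r = icc_mean_squares_oracle(x)
        assert abs(res["icc_single"] - single) < 1e-10
        assert abs(res["icc_mean"] - mean_r) < 1e-10
        assert res["icc_single"] <= 1 and res["icc_mean"] <= 1

    def test_matches_pingouin_reference(self):
        """Estimates and CIs agree with the published ICC2/ICC2k routines."""
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        r = np.random.default_rng(5)
        x = r.standard_normal((12, 3)) + 2 * r.standard_normal((12, 1))
        res = icc_two_way_random(RatingTable(x))
        long = pd.DataFrame({
            "subject": np.repeat(np.arange(12), 3),
            "rater": np.tile(np.arange(3), 12),
            "score": x.ravel(),
        })
        ref = pingouin.intraclass_corr(long, targets="subject", raters="rater",
                                       ratings="score").set_index("Type")
        ci_col = "CI95%" if "CI95%" in ref.columns else "CI95"
        assert res["icc_single"] == pytest.approx(ref.loc["ICC(A,1)", "ICC"], abs=1e-10)
        assert res["icc_mean"] == pytest.approx(ref.loc["ICC(A,k)", "ICC"], abs=1e-10)
        # pingouin rounds the CI bounds to two decimals
        assert res["ci95_single"] == pytest.approx(tuple(ref.loc["ICC(A,1)", ci_col]),
                                                   abs=1.1e-2)
        assert res["ci95_mean"] == pytest.approx(tuple(ref.loc["ICC(A,k)", ci_col]),
                                                 abs=1.1e-2)

    def test_independent_raters_near_zero(self):
        r = np.random.default_rng(0)
        res = icc_two_way_random(RatingTable(r.standard_normal((1000, 2))))
        assert abs(res["icc_single"]) < 0.1

    def test_zero_variance_degenerate(self):
        with pytest.raises(DegenerateInputError):
            icc_two_way_random(RatingTable(np.full((5, 2), 3.0)))


def auroc_pairwise_oracle(scores, labels):
    """Exhaustive concordance probability with tie credit 1/2."""
    s = np.asarray(scores, float)
    y = np.asarray(labels, int)
    pos, neg = s[y == 1], s[y == 0]
    wins = (pos[:, None] > neg[None, :]).sum() + 0.5 * (pos[:, None] == neg[None, :]).sum()
    return wins / (len(pos) * len(neg))


class TestROC:
    def test_perfect_separation(self):
        res = roc_analysis([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1], n_boot=50)
        assert res["auroc"] == 1.0

    def test_small_example(self):
        res = roc_analysis([1, 3, 2, 4], [0, 0, 1, 1], n_boot=50)
        assert res["auroc"] == pytest.approx(0.75)

    @pytest.mark.parametrize("seed", range(10))
    def test_equals_pairwise_concordance(self, seed):
        r = np.random.default_rng(seed)
        n = int(r.integers(6, 51))
        scores = np.round(r.standard_normal(n), 1)  # rounding forces ties
        labels = r.integers(0, 2, n)
        if len(np.unique(labels)) < 2:
            labels[0], labels[1] = 0, 1
        res = roc_analysis(scores, labels, n_boot=10)
        assert res["auroc"] == pytest.approx(auroc_pairwise_oracle(scores, labels),
                                             abs=1e-12)

    def test_contingency_arithmetic(self):
        m = operating_point_metrics(tp=8, fn=2, tn=9, fp=1)
        assert m["sens"] == pytest.approx(0.8)
        assert m["spec"] == pytest.approx(0.9)
        assert m["lr_pos"] == pytest.approx(8.0)

    def test_single_class_rejected(self):
        with pytest.raises(InputError):
            roc_analysis([1, 2, 3], [1, 1, 1])

    def test_youden_cutoff_calls_positive_inclusively(self):
        res = roc_analysis([1.0, 2.0, 3.0, 4.0], [0, 0, 1, 1], n_boot=10)
        assert res["cutoff"] == pytest.approx(3.0)
        assert res["sens"] == 1.0 and res["spec"] == 1.0


class TestCorrelationRegression:
    def test_exact_line(self):
        x = np.arange(10.0)
        res = correlation_regression(x, 2 * x + 1)
        assert res["spearman_rho"] == pytest.approx(1.0)
        assert res["r_squared_pct"] == pytest.approx(100.0)
        assert res["slope"] == pytest.approx(2.0)
        assert res["intercept"] == pytest.approx(1.0)

    def test_reversed_ranks(self):
        x = np.arange(8.0)
        assert correlation_regression(x, -x)["spearman_rho"] == pytest.approx(-1.0)

    def test_rank_formula_example(self):
        res = correlation_regression([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
        # 1 - 6*sum(d^2)/(n(n^2-1)) with d = (-1,1,-1,1,0)
        assert res["spearman_rho"] == pytest.approx(0.8)

    def test_constant_input_degenerate(self):
        with pytest.raises(DegenerateInputError):
            correlation_regression([1, 1, 1, 1], [1, 2, 3, 4])


class TestSynthCohort:
    def test_marginal_mean_recovered(self):
        df = synth_cohort(10_000, seed=3)
        se = COHORT_MARGINALS["pdff"]["sd"] / np.sqrt(10_000)
        # clipping at 0 shifts the mean slightly upward; stay within 3 SE
        assert abs(df["pdff"].mean() - 11.16) < 3 * se + 0.2
        assert df.shape[1] == 7

    def test_independence_limit(self):
        df = synth_cohort(10_000, rho_ac_pdff=0.0, seed=4)
        assert abs(np.corrcoef(df["pdff"], df["qus_ac"])[0, 1]) < 0.05

    def test_copula_rank_correlation(self):
        from scipy.stats import spearmanr

        rho = 0.9
        df = synth_cohort(10_000, rho_ac_pdff=rho, seed=5)
        implied = 6 / np.pi * np.arcsin(rho / 2)
        assert spearmanr(df["pdff"], df["qus_ac"])[0] == pytest.approx(implied, abs=0.03)

    def test_invalid_rho_rejected(self):
        with pytest.raises(ConfigurationError):
            synth_cohort(10, rho_ac_pdff=1.0)

    def test_end_to_end_grading_discrimination(self):
        """High AC-PDFF coupling yields a discriminative AC; rho=0 does not."""
        aurocs = {}
        for rho in (0.0, 0.9):
            df = synth_cohort(2000, rho_ac_pdff=rho, seed=6)
            labels = (df["pdff"].map(grade_from_pdff) >= 1).astype(int).to_numpy()
            aurocs[rho] = roc_analysis(df["qus_ac"].to_numpy(), labels, n_boot=10)["auroc"]
        assert aurocs[0.9] > aurocs[0.0] + 0.2
        assert aurocs[0.9] > 0.8
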