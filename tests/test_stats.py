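"""Agreement statistics: normality gate, paired tests, ICC, Bland-Altman."""

from itertools import product

import numpy as np
import pandas as pd
import pingouin as pg
import pytest
import scipy.stats as sps
from hypothesis import given, settings, strategies as st
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm

from octagree.stats import (
    PairedSample,
    bland_altman,
    icc_agreement,
    normality_gate,
    paired_test,
    summarize,
    wilcoxon_signed_rank,
)


def enum_signed_rank_p(d):
    """Brute-force two-sided signed-rank p over all 2^n sign assignments."""
    d = np.asarray(d, float)
    d = d[d != 0]
    ranks = sps.rankdata(np.abs(d))
    obs = ranks[d > 0].sum()
    total = ranks.sum()
    stat = min(obs, total - obs)
    count = 0
    for signs in product((0, 1), repeat=len(d)):
        w = sum(r for r, s in zip(ranks, signs) if s)
        if w <= stat + 1e-9 or w >= total - stat - 1e-9:
            count += 1
    return count / 2 ** len(d)


def anova_mean_squares_icc(table):
    """Independent ICC(A,1) oracle via statsmodels two-way ANOVA."""
    n, k = table.shape
    df = pd.DataFrame(
        {"y": table.ravel(),
         "subject": np.repeat(np.arange(n), k).astype(str),
         "rater": np.tile(np.arange(k), n).astype(str)}
    )
    aov = anova_lm(ols("y ~ C(subject) + C(rater)", data=df).fit())
    msr = aov.loc["C(subject)", "mean_sq"]
    msc = aov.loc["C(rater)", "mean_sq"]
    mse = aov.loc["Residual", "mean_sq"]
    return (msr - mse) / (msr + (k - 1) * mse + (k / n) * (msc - mse))


class TestNormalityGate:
    def test_gaussian_sample_passes(self):
        d = np.random.default_rng(1).normal(0, 1, 200)
        assert normality_gate(d).branch == "normal"

    def test_two_point_sample_fails(self):
        d = np.random.default_rng(2).choice([0.0, 10.0], size=200)
        assert normality_gate(d).branch == "non-normal"

    def test_constant_vector_degenerate(self):
        res = normality_gate(np.zeros(20))
        assert res.branch == "non-normal" and res.flags


class TestPairedTest:
    def test_identical_vectors_p_one(self):
        s = PairedSample(np.arange(10.0), np.arange(10.0))
        for branch in ("normal", "non-normal"):
            res = paired_test(s, branch)
            assert res.p_value == 1.0 and res.flags

    def test_all_positive_n6_exact(self):
        s = PairedSample(np.zeros(6), np.array([1.0, 2, 3, 4, 5, 6]))
        res = paired_test(s, "non-normal")
        assert res.p_value == pytest.approx(2 / 64)

    def test_constant_nonzero_differences_degenerate_t(self):
        s = PairedSample(np.zeros(4), np.ones(4))
        res = paired_test(s, "normal")
        assert np.isnan(res.p_value) and res.flags


class TestSignedRank:
    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(st.lists(st.integers(-5, 5), min_size=3, max_size=12))
    def test_exact_branch_matches_enumeration(self, diffs):
        d = np.asarray(diffs, float)
        if np.all(d == 0):
            return
        assert wilcoxon_signed_rank(d).p_value == pytest.approx(
            enum_signed_rank_p(d), abs=1e-12
        )

    def test_matches_scipy_exact_without_ties(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            d = rng.permutation(np.arange(1, 16)) * rng.choice([-1, 1], 15)
            ours = wilcoxon_signed_rank(d.astype(float)).p_value
            theirs = sps.wilcoxon(d, method="exact").pvalue
            assert ours == pytest.approx(theirs, abs=1e-12)

    def test_matches_scipy_normal_approximation(self):
        rng = np.random.default_rng(4)
        d = rng.normal(0.3, 1.0, 40)
        ours = wilcoxon_signed_rank(d).p_value
        theirs = sps.wilcoxon(d, method="approx", correction=True).pvalue
        assert ours == pytest.approx(theirs, rel=1e-9)


class TestICC:
    def test_duplicated_measurements_give_unity(self):
        x = np.array([3.0, 7, 1, 9, 4, 6])
        res = icc_agreement(np.column_stack([x, x]))
        assert res.icc == 1.0

    def test_absolute_agreement_below_consistency_under_offset(self):
        rng = np.random.default_rng(5)
        x = rng.normal(10, 0.5, 12)
        table = np.column_stack([x, x + 5.0 + rng.normal(0, 0.1, 12)])
        icc_a = icc_agreement(table, form="agreement").icc
        icc_c = icc_agreement(table, form="consistency").icc
        assert icc_a < icc_c

    def test_matches_independent_anova_oracle(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            n = int(rng.integers(5, 61))
            table = rng.normal(0, 1, (n, 2)) + rng.normal(0, 1, (n, 1))
            assert icc_agreement(table).icc == pytest.approx(
                anova_mean_squares_icc(table), abs=1e-10
            )

    def test_matches_pingouin_value_and_ci(self):
        rng = np.random.default_rng(7)
        table = rng.normal(10, 3, (20, 2)) + rng.normal(0, 2, (20, 1))
        res = icc_agreement(table)
        df = pd.DataFrame(
            {"subj": np.repeat(np.arange(20), 2), "rater": np.tile([0, 1], 20),
             "y": table.ravel()}
        )
        row = pg.intraclass_corr(df, targets="subj", raters="rater",
                                 ratings="y").set_index("Type").loc["ICC(A,1)"]
        assert res.icc == pytest.approx(row["ICC"], abs=1e-10)
        np.testing.assert_allclose([res.ci_lower, res.ci_upper], row["CI95"],
                                   atol=5e-3)  # pingouin rounds its CI

    def test_zero_between_subject_variance_flagged(self):
        res = icc_agreement(np.full((6, 2), 4.2))
        assert res.icc == 0.0 and res.flags


class TestBlandAltman:
    def test_all_zero_differences(self):
        res = bland_altman(np.zeros(12), "non-normal")
        assert (res.center, res.lower, res.upper, res.n_outside) == (0, 0, 0, 0)

    def test_parametric_limits_formula(self):
        d = np.array([1.0, 2, 3, 4, 10])
        res = bland_altman(d, "normal")
        assert res.center == pytest.approx(d.mean())
        assert res.upper == pytest.approx(d.mean() + 1.96 * d.std(ddof=1))

    def test_quantile_branch_against_order_statistic_oracle(self):
        d = np.arange(1.0, 101.0)
        res = bland_altman(d, "non-normal", quantile_estimator="order-statistic")
        lo, hi = np.quantile(d, [0.025, 0.975])
        assert res.center == 50.5
        assert (res.lower, res.upper) == (lo, hi)
        # Harrell-Davis default lands on the same bracket, smoothly
        hd = bland_altman(d, "non-normal")
        assert hd.lower == pytest.approx(3.0, abs=0.5)
        assert hd.upper == pytest.approx(98.0, abs=0.5)

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(st.floats(0.1, 10.0), st.floats(-50.0, 50.0), st.integers(0, 1000))
    def test_quantile_loa_affine_equivariance(self, a, b, seed):
        d = np.random.default_rng(seed).normal(0, 5, 40)
        base = bland_altman(d, "non-normal")
        mapped = bland_altman(a * d + b, "non-normal")
        assert mapped.center == pytest.approx(a * base.center + b, rel=1e-9, abs=1e-9)
        assert mapped.lower == pytest.approx(a * base.lower + b, rel=1e-9, abs=1e-9)
        assert mapped.upper == pytest.approx(a * base.upper + b, rel=1e-9, abs=1e-9)

    def test_outside_count_is_strict(self):
        d = np.array([0.0] * 8 + [5.0, -5.0])
        res = bland_altman(d, "non-normal", quantile_estimator="order-statistic")
        assert res.n_outside == int(np.sum((d < res.lower) | (d > res.upper)))


class TestSummarize:
    def test_identical_modes_single_subgroup(self):
        x = np.array([3.0, 7, 1, 9, 4, 6])
        s = PairedSample(x, x.copy())
        out = summarize(s, biomarker="hf")
        assert out.mean_difference == 0.0
        assert out.p_value == 1.0
        assert out.icc.icc == 1.0

    def test_small_subgroup_omits_icc(self):
        s = PairedSample(np.array([1.0, 2, 3, 4]), np.array([1.5, 2.5, 2.0, 4.5]))
        out = summarize(s)
        assert out.icc is None
        assert any("ICC omitted" in f for f in out.flags)

    def test_subgroup_mask_filters_rows(self):
        rng = np.random.default_rng(8)
        a = rng.normal(10, 2, 12)
        b = a + rng.normal(0, 0.5, 12)
        labels = pd.DataFrame({"eye_id": [f"e{i}" for i in range(12)]})
        s = PairedSample(a, b, labels)
        mask = np.arange(12) < 6
        out = summarize(s, subgroup="With ME", subgroup_mask=mask)
        assert out.n == 6
        assert out.mean_difference == pytest.approx((b - a)[:6].mean())

    def test_duplicated_subject_ids_rejected(self):
        labels = pd.DataFrame({"eye_id": ["a", "a", "b"]})
        with pytest.raises(ValueError, match="duplicated"):
            PairedSample(np.zeros(3), np.ones(3), labels)
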