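"""Reliability and comparison statistics against independent oracles."""

import numpy as np
import pytest
from scipy import stats as sps

from suprafat import (
    GradeGroupSummary,
    RatingsMatrix,
    anova_power_from_summary,
    correlation_power,
    cv_across_observers,
    icc,
    one_way_anova,
    pearson,
    tukey_hsd,
)
from suprafat.errors import InputError, UndefinedStatisticError


def icc21_by_hand(x):
    """Mean-squares decomposition written out longhand as an oracle."""
    n, k = x.shape
    grand = x.mean()
    msr = k * sum((x[i].mean() - grand) ** 2 for i in range(n)) / (n - 1)
    msc = n * sum((x[:, j].mean() - grand) ** 2 for j in range(k)) / (k - 1)
    sse = sum(
        (x[i, j] - x[i].mean() - x[:, j].mean() + grand) ** 2
        for i in range(n) for j in range(k)
    )
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n), (msr, msc, mse)


class TestIcc:
    def test_identical_observers_give_one(self):
        subj = np.array([1.0, 5.0, 9.0, 4.0])
        x = np.tile(subj[:, None], (1, 3))
        r = icc(RatingsMatrix(x))
        assert r.icc == pytest.approx(1.0)
        assert r.ci_low <= r.icc <= r.ci_high

    def test_constant_offsets_reduce_absolute_agreement(self, rng):
        subj = rng.normal(100, 30, 10)
        x = subj[:, None] + np.array([0.0, 5.0, -5.0])
        r = icc(RatingsMatrix(x))
        assert r.icc < 1.0
        # consistency-type ICC(3,1) ignores the rater offsets entirely
        msr, msc, mse = r.mean_squares
        icc31 = (msr - mse) / (msr + 2 * mse)
        assert icc31 == pytest.approx(1.0)

    def test_matches_hand_mean_squares_oracle(self):
        x = np.array([
            [9, 2, 5, 8],
            [6, 1, 3, 2],
            [8, 4, 6, 8],
            [7, 1, 2, 6],
            [10, 5, 6, 9],
            [6, 2, 4, 7],
        ], dtype=float)
        r = icc(RatingsMatrix(x))
        expected, ms = icc21_by_hand(x)
        assert r.icc == pytest.approx(expected, rel=1e-12)
        assert r.mean_squares == pytest.approx(ms, rel=1e-12)

    def test_matches_pingouin_icc2_with_ci(self, rng):
        import pandas as pd
        import pingouin as pg

        subj = rng.normal(50, 10, 12)
        x = subj[:, None] + rng.normal(0, 2, (12, 4))
        r = icc(RatingsMatrix(x))
        df = pd.DataFrame(x).reset_index().melt("index", var_name="rater",
                                                value_name="v")
        table = pg.intraclass_corr(df, targets="index", raters="rater", ratings="v")
        row = table[table["Type"] == "ICC(A,1)"].iloc[0]
        assert r.icc == pytest.approx(row["ICC"], abs=1e-9)
        assert r.ci_low == pytest.approx(row["CI95"][0], abs=0.005)
        assert r.ci_high == pytest.approx(row["CI95"][1], abs=0.005)

    def test_average_form_exceeds_single(self, rng):
        subj = rng.normal(0, 5, 8)
        x = subj[:, None] + rng.normal(0, 2, (8, 3))
        single = icc(RatingsMatrix(x)).icc
        avg = icc(RatingsMatrix(x), average=True).icc
        assert avg >= single

    def test_additive_constant_invariance(self, rng):
        x = rng.normal(10, 3, (7, 3))
        r1 = icc(RatingsMatrix(x))
        r2 = icc(RatingsMatrix(x + 42.0))
        assert r1.icc == pytest.approx(r2.icc, abs=1e-10)

    def test_zero_variance_raises(self):
        with pytest.raises(UndefinedStatisticError):
            icc(RatingsMatrix(np.full((4, 3), 2.0)))


class TestCv:
    def test_identical_observers_zero(self):
        df = cv_across_observers(RatingsMatrix(np.tile([[4.0, 4.0, 4.0]], (3, 1))))
        assert np.allclose(df["cv_percent"], 0.0)

    def test_hand_example(self):
        df = cv_across_observers(RatingsMatrix(np.array([[90.0, 100.0, 110.0],
                                                         [50.0, 50.0, 50.0]])))
        assert df["cv_percent"].iloc[0] == pytest.approx(10.0)
        assert df.attrs["range"] == (0.0, pytest.approx(10.0))

    def test_scale_invariance(self, rng):
        x = rng.uniform(10, 20, (5, 4))
        cv1 = cv_across_observers(RatingsMatrix(x))["cv_percent"]
        cv2 = cv_across_observers(RatingsMatrix(3 * x))["cv_percent"]
        assert np.allclose(cv1, cv2)

    def test_nonpositive_values_raise(self):
        with pytest.raises(UndefinedStatisticError):
            cv_across_observers(RatingsMatrix(np.array([[1.0, -1.0], [2.0, 3.0]])))


class TestAnova:
    def test_identical_groups(self):
        f, df1, df2, p = one_way_anova([[1, 2, 3], [1, 2, 3], [1, 2, 3]])
        assert f == 0.0
        assert p == 1.0

    def test_two_groups_equal_t_squared(self, rng):
        a, b = rng.normal(0, 1, 8), rng.normal(0.5, 1, 10)
        f, _, _, p = one_way_anova([a, b])
        t, pt = sps.ttest_ind(a, b)
        assert f == pytest.approx(t**2, rel=1e-10)
        assert p == pytest.approx(pt, rel=1e-10)

    def test_hand_computed_toy(self):
        # groups (1,2,3), (2,3,4), (6,7,8): SSB = 42, SSW = 6, F = 21
        f, df1, df2, p = one_way_anova([[1, 2, 3], [2, 3, 4], [6, 7, 8]])
        assert f == pytest.approx(21.0, rel=1e-12)
        assert (df1, df2) == (2, 6)
        assert p == pytest.approx(float(sps.f.sf(21.0, 2, 6)), rel=1e-12)

    def test_matches_scipy(self, rng):
        groups = [rng.normal(m, 1, n) for m, n in [(0, 5), (1, 8), (0.5, 6)]]
        f, _, _, p = one_way_anova(groups)
        res = sps.f_oneway(*groups)
        assert f == pytest.approx(res.statistic, rel=1e-12)
        assert p == pytest.approx(res.pvalue, rel=1e-12)

    def test_zero_within_variance_boundary(self):
        f, _, _, p = one_way_anova([[1.0, 1.0], [2.0, 2.0]])
        assert np.isinf(f)
        assert 0.0 < p < 1e-300


class TestTukey:
    def test_identical_group_means(self):
        t = tukey_hsd([[1, 2, 3], [1, 2, 3], [1, 2, 3]])
        assert np.allclose(t["p_adj"], 1.0)
        assert np.allclose(t["q"], 0.0)

    def test_symmetric_under_group_order(self, rng):
        groups = [rng.normal(m, 1, 6) for m in (0, 1, 2)]
        t1 = tukey_hsd(groups, labels=["a", "b", "c"])
        t2 = tukey_hsd(groups[::-1], labels=["c", "b", "a"])
        p1 = {frozenset((r.group_a, r.group_b)): r.p_adj for r in t1.itertuples()}
        p2 = {frozenset((r.group_a, r.group_b)): r.p_adj for r in t2.itertuples()}
        assert p1 == pytest.approx(p2)

    def test_matches_scipy_tukey_hsd(self, rng):
        groups = [rng.normal(m, 1.5, n) for m, n in [(0, 5), (1.2, 9), (2.5, 7)]]
        mine = tukey_hsd(groups)
        theirs = sps.tukey_hsd(*groups)
        for row in mine.itertuples():
            i, j = int(row.group_a[1]), int(row.group_b[1])
            assert row.p_adj == pytest.approx(theirs.pvalue[i, j], abs=1e-8)

    def test_agrees_with_anova_direction(self, rng):
        displaced = [rng.normal(0, 1, 8), rng.normal(0, 1, 8), rng.normal(4, 1, 8)]
        _, _, _, p_anova = one_way_anova(displaced)
        p_min = tukey_hsd(displaced)["p_adj"].min()
        assert (p_anova < 0.05) == (p_min < 0.05)


class TestPearson:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        r, r2, p = pearson(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        assert r2 == pytest.approx(1.0)

    def test_perfect_negative(self):
        x = np.arange(5.0)
        assert pearson(x, -x)[0] == pytest.approx(-1.0)

    def test_hand_formula_toy(self):
        x = np.array([1.0, 2, 3, 4, 5])
        y = np.array([2.0, 1, 4, 3, 6])
        expected = float(((x - x.mean()) * (y - y.mean())).sum()
                         / np.sqrt(((x - x.mean()) ** 2).sum()
                                   * ((y - y.mean()) ** 2).sum()))
        r, r2, p = pearson(x, y)
        assert r == pytest.approx(expected, rel=1e-12)
        assert r2 == pytest.approx(expected**2, rel=1e-12)
        # p via the t transform
        t = expected * np.sqrt(3 / (1 - expected**2))
        assert p == pytest.approx(2 * sps.t.sf(abs(t), 3), rel=1e-9)

    def test_zero_variance_raises(self):
        with pytest.raises(UndefinedStatisticError):
            pearson([1, 1, 1], [1, 2, 3])


def mc_anova_power(ns, means, sds, alpha, n_sims, rng):
    """Monte-Carlo rejection rate of the one-way F test (vectorized)."""
    k = len(ns)
    n_total = sum(ns)
    group_means, group_ss = [], []
    grand_sum = np.zeros(n_sims)
    for n, m, s in zip(ns, means, sds):
        x = rng.normal(m, s, (n_sims, n))
        group_means.append(x.mean(axis=1))
        group_ss.append(((x - x.mean(axis=1, keepdims=True)) ** 2).sum(axis=1))
        grand_sum += x.sum(axis=1)
    grand = grand_sum / n_total
    ssb = sum(n * (gm - grand) ** 2 for n, gm in zip(ns, group_means))
    ssw = sum(group_ss)
    f = (ssb / (k - 1)) / (ssw / (n_total - k))
    return float((f > sps.f.ppf(1 - alpha, k - 1, n_total - k)).mean())


class TestAnovaPower:
    def test_equal_means_give_alpha(self):
        s = GradeGroupSummary(grades=(0, 1, 2), n=(5, 5, 5),
                              mean=(2.0, 2.0, 2.0),
                              ci_low=(1.0, 1.0, 1.0), ci_high=(3.0, 3.0, 3.0))
        assert anova_power_from_summary(s).power == pytest.approx(0.05)

    def test_matches_monte_carlo(self, rng):
        s = GradeGroupSummary(grades=(0, 1, 2), n=(6, 8, 7),
                              mean=(10.0, 12.0, 14.5),
                              ci_low=(7.5, 9.8, 12.0), ci_high=(12.5, 14.2, 17.0))
        analytic = anova_power_from_summary(s).power
        sds = [  # same CI inversion the implementation documents
            (hi - lo) / 2 * np.sqrt(n) / sps.t.ppf(0.975, n - 1)
            for lo, hi, n in zip(s.ci_low, s.ci_high, s.n)
        ]
        # MC uses per-group SDs; analytic pools them -- same model at these SDs
        mc = mc_anova_power(s.n, s.mean, sds, 0.05, 20000, rng)
        assert analytic == pytest.approx(mc, abs=0.02)

    def test_power_monotone_in_separation(self):
        def summary(spread):
            return GradeGroupSummary(
                grades=(0, 1), n=(8, 8),
                mean=(10.0 - spread, 10.0 + spread),
                ci_low=(10.0 - spread - 2, 10.0 + spread - 2),
                ci_high=(10.0 - spread + 2, 10.0 + spread + 2),
            )
        p1 = anova_power_from_summary(summary(1.0)).power
        p2 = anova_power_from_summary(summary(2.0)).power
        assert 0.05 <= p1 < p2 <= 1.0

    def test_tiny_groups_raise(self):
        s = GradeGroupSummary(grades=(0, 1), n=(1, 5), mean=(1.0, 2.0),
                              ci_low=(0.5, 1.5), ci_high=(1.5, 2.5))
        with pytest.raises(InputError):
            anova_power_from_summary(s)


class TestCorrelationPower:
    def test_null_effect_gives_alpha(self):
        assert correlation_power(0.0, 30).power == pytest.approx(0.05)

    def test_matches_monte_carlo(self, rng):
        r, n = 0.5, 30
        analytic = correlation_power(r, n).power
        n_sims = 20000
        x = rng.standard_normal((n_sims, n))
        y = r * x + np.sqrt(1 - r**2) * rng.standard_normal((n_sims, n))
        xm = x - x.mean(axis=1, keepdims=True)
        ym = y - y.mean(axis=1, keepdims=True)
        rh = (xm * ym).sum(axis=1) / np.sqrt((xm**2).sum(axis=1) * (ym**2).sum(axis=1))
        t = rh * np.sqrt((n - 2) / (1 - rh**2))
        mc = float((2 * sps.t.sf(np.abs(t), n - 2) < 0.05).mean())
        assert analytic == pytest.approx(mc, abs=0.02)

    def test_monotone_in_n_and_r(self):
        assert correlation_power(0.4, 60).power > correlation_power(0.4, 20).power
        assert correlation_power(0.6, 20).power > correlation_power(0.4, 20).power

    def test_rejects_degenerate_r(self):
        with pytest.raises(InputError):
            correlation_power(1.0, 30)


class TestRatingsMatrix:
    def test_from_dataframe(self):
        import pandas as pd

        df = pd.DataFrame({"o1": [1.0, 2.0], "o2": [1.5, 2.5]}, index=["a", "b"])
        m = RatingsMatrix.from_dataframe(df)
        assert m.subject_ids == ("a", "b")
        assert m.observer_ids == ("o1", "o2")

    @pytest.mark.parametrize("shape", [(1, 3), (3, 1)])
    def test_rejects_degenerate_shapes(self, shape):
        with pytest.raises(InputError):
            RatingsMatrix(np.ones(shape))

    def test_rejects_missing_cells(self):
        with pytest.raises(InputError):
            RatingsMatrix(np.array([[1.0, np.nan], [2.0, 3.0]]))
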