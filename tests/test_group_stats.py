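"""Group-comparison statistics: t-tests, Fisher exact, ICC, two-way ANOVA."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import comb

from echosway.group_stats import (
    SummaryStats,
    anova_condition_by_age,
    bonferroni,
    fisher_exact_2x2,
    icc_test_retest,
    label_correlation_strength,
    ttest_from_summary,
    ttest_raw,
)


class TestSummaryTTest:
    # published group summaries that are rounding-consistent with their
    # printed t statistics
    @pytest.mark.parametrize(
        "s, t_expect, d_expect",
        [
            (SummaryStats(32, 173.0, 10.0, 34, 166.4, 9.4, "height"), 2.75, None),
            (SummaryStats(32, 2.21, 0.48, 34, 1.38, 0.33, "VL MT"), 8.22, 2.0),
            (SummaryStats(32, 32.3, 7.1, 34, 56.0, 9.2, "VL EI"), -11.6, 2.9),
            (SummaryStats(32, 30.0, 6.9, 34, 42.3, 8.4, "BB EI"), -6.48, None),
            (SummaryStats(32, 7.33, 0.66, 34, 8.09, 0.39, "BB Entropy"), None, 1.4),
        ],
    )
    def test_reproduces_published_statistics(self, s, t_expect, d_expect):
        res = ttest_from_summary(s)
        assert res.df == 64
        # tolerance: printed precision plus the rounding of the printed
        # summary inputs themselves
        if t_expect is not None:
            assert res.t == pytest.approx(t_expect, abs=0.1)
        if d_expect is not None:
            assert res.cohens_d == pytest.approx(d_expect, abs=0.05)

    def test_equal_groups_null(self):
        res = ttest_from_summary(SummaryStats(10, 5.0, 1.0, 12, 5.0, 2.0))
        assert res.t == 0.0 and res.p == 1.0 and res.cohens_d == 0.0

    def test_zero_pooled_sd_overflow_sentinel(self):
        res = ttest_from_summary(SummaryStats(5, 2.0, 0.0, 5, 1.0, 0.0))
        assert math.isinf(res.t) and res.p == 0.0


class TestRawTTest:
    def test_identical_samples(self):
        res = ttest_raw([1, 2, 3], [1, 2, 3])
        assert res.t == 0.0

    def test_raw_equals_summary_path(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            x1 = rng.normal(0, 1, size=20)
            x2 = rng.normal(0.5, 2, size=25)
            raw = ttest_raw(x1, x2)
            summ = ttest_from_summary(SummaryStats(
                20, x1.mean(), x1.std(ddof=1), 25, x2.mean(), x2.std(ddof=1)))
            assert raw.t == pytest.approx(summ.t, abs=1e-12)
            assert raw.p == pytest.approx(summ.p, abs=1e-12)

    def test_shift_monotone_in_t(self):
        rng = np.random.default_rng(1)
        x2 = rng.normal(size=15)
        x1 = rng.normal(size=15)
        ts = [ttest_raw(x1 + c, x2).t for c in (0.0, 0.5, 1.0, 2.0)]
        assert all(a < b for a, b in zip(ts, ts[1:]))

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError, match="n >= 2"):
            ttest_raw([1.0], [1, 2, 3])

    def test_agrees_with_scipy(self):
        from scipy import stats
        rng = np.random.default_rng(2)
        x1, x2 = rng.normal(size=12), rng.normal(0.7, 1, size=17)
        res = ttest_raw(x1, x2)
        ref = stats.ttest_ind(x1, x2, equal_var=True)
        assert res.t == pytest.approx(ref.statistic, abs=1e-12)
        assert res.p == pytest.approx(ref.pvalue, abs=1e-12)


def enumeration_fisher(a, b, c, d):
    """Independent oracle: full hypergeometric enumeration at fixed margins."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    def prob(x):
        return comb(r1, x, exact=True) * comb(r2, c1 - x, exact=True) / comb(n, c1, exact=True)
    p_obs = prob(a)
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        px = prob(x)
        if px <= p_obs * (1 + 1e-12):
            total += px
    return min(1.0, total)


class TestFisherExact:
    def test_study_sex_table_matches_enumeration(self):
        # 15/32 vs 18/34 women: two-sided p rounds to the published 0.81
        p = fisher_exact_2x2(15, 17, 18, 16)
        assert p == pytest.approx(enumeration_fisher(15, 17, 18, 16), abs=1e-10)
        assert p == pytest.approx(0.806, abs=0.001)

    def test_symmetric_table_gives_one(self):
        assert fisher_exact_2x2(10, 10, 10, 10) == 1.0

    def test_extreme_table_closed_form(self):
        # only the two perfectly separated tables are as extreme
        p = fisher_exact_2x2(10, 0, 0, 10)
        assert p == pytest.approx(2 / comb(20, 10, exact=True), rel=1e-9)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2(-1, 2, 3, 4)


class TestICC:
    def test_identical_replicates_give_one(self):
        rng = np.random.default_rng(0)
        vals = np.tile(rng.normal(size=(12, 1)), (1, 3))
        assert icc_test_retest(vals).icc == pytest.approx(1.0, abs=1e-9)

    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(1)
        res = icc_test_retest(rng.standard_normal((200, 3)))
        assert abs(res.icc) < 0.1
        assert res.ci95[0] <= res.icc <= res.ci95[1]

    def test_variance_ratio_recovered(self):
        # sigma_b = 3, sigma_w = 1 -> icc = 9/10
        rng = np.random.default_rng(3)
        vals = 3.0 * rng.standard_normal((400, 1)) + rng.standard_normal((400, 3))
        assert icc_test_retest(vals).icc == pytest.approx(0.9, abs=0.03)

    def test_matches_mean_squares_closed_form(self):
        # independent oracle: ICC(2,1) from the two-way mean squares
        rng = np.random.default_rng(4)
        vals = 1.5 * rng.standard_normal((30, 1)) + rng.standard_normal((30, 4))
        n, k = vals.shape
        grand = vals.mean()
        msr = k * np.sum((vals.mean(axis=1) - grand) ** 2) / (n - 1)
        msc = n * np.sum((vals.mean(axis=0) - grand) ** 2) / (k - 1)
        sse = np.sum((vals - vals.mean(1, keepdims=True) - vals.mean(0) + grand) ** 2)
        mse = sse / ((n - 1) * (k - 1))
        expected = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
        assert icc_test_retest(vals).icc == pytest.approx(expected, abs=1e-9)

    def test_too_few_replicates_rejected(self):
        with pytest.raises(ValueError):
            icc_test_retest(np.ones((5, 1)))


def _sway_table(rng, cond_effects, group_gap=1.0, n_per_group=24, noise=0.3):
    rows = []
    for g, base in (("young", 2.0), ("old", 2.0 + group_gap)):
        for s in range(n_per_group):
            for cond, extra in cond_effects.items():
                rows.append({"subject": f"{g}{s}", "group": g, "condition": cond,
                             "sdCOP_AP_norm": base + extra + noise * rng.standard_normal()})
    return pd.DataFrame(rows)


class TestAnova:
    def test_planted_hardest_condition_posthoc(self):
        rng = np.random.default_rng(5)
        table = _sway_table(rng, {"EOhard": 0.0, "EChard": 0.2, "EOfoam": 0.5, "ECfoam": 1.5})
        res = anova_condition_by_age(table)
        assert res.effects.loc["condition", "p"] < 1e-6
        ph = res.posthoc
        ec = ph[(ph.cond_a == "ECfoam") | (ph.cond_b == "ECfoam")]
        assert (ec.p_bonferroni < 0.05).all()

    def test_ss_decomposition_balanced(self):
        rng = np.random.default_rng(6)
        table = _sway_table(rng, {"EOhard": 0.0, "EChard": 0.3, "EOfoam": 0.6, "ECfoam": 1.0})
        res = anova_condition_by_age(table)
        assert res.effects["eta_squared"].sum() <= 1.0
        # eta^2 ratios imply SS_effects + SS_error = SS_total by construction;
        # verify via the model recomputation
        y = table["sdCOP_AP_norm"].to_numpy()
        ss_total = np.sum((y - y.mean()) ** 2)
        import statsmodels.api as sm
        from statsmodels.formula.api import ols
        aov = sm.stats.anova_lm(
            ols("sdCOP_AP_norm ~ C(condition) * C(group)", data=table).fit(), typ=2)
        assert aov["sum_sq"].sum() == pytest.approx(ss_total, rel=1e-9)

    def test_null_condition_type_one_error(self):
        # no condition effect planted: condition F should reject ~5% of the time
        rng = np.random.default_rng(7)
        rej = 0
        runs = 200
        for _ in range(runs):
            table = _sway_table(rng, {c: 0.0 for c in ("EOhard", "EChard", "EOfoam", "ECfoam")},
                                n_per_group=10)
            res = anova_condition_by_age(table)
            rej += res.effects.loc["condition", "p"] < 0.05
        assert 0.02 <= rej / runs <= 0.09

    def test_constant_data_gives_zero_f(self):
        rows = [{"subject": f"s{s}{g}", "group": g, "condition": c, "sdCOP_AP_norm": 1.0}
                for g in ("young", "old") for s in range(5)
                for c in ("EOhard", "EChard", "EOfoam", "ECfoam")]
        res = anova_condition_by_age(pd.DataFrame(rows))
        assert (res.effects["F"] == 0).all()
        assert (res.effects["p"] == 1).all()

    def test_empty_cell_named_in_error(self):
        rows = [{"subject": "a", "group": "young", "condition": "EOhard", "sdCOP_AP_norm": 1.0},
                {"subject": "b", "group": "old", "condition": "EChard", "sdCOP_AP_norm": 2.0}]
        with pytest.raises(ValueError, match="empty design cells"):
            anova_condition_by_age(pd.DataFrame(rows))


class TestLabelsAndBonferroni:
    @pytest.mark.parametrize("r, label", [
        (0.0, "very weak"), (0.19, "very weak"), (0.25, "weak"),
        (0.53, "moderate"), (0.65, "strong"), (0.80, "very strong"),
        (-0.9, "very strong"), (1.0, "very strong"),
    ])
    def test_strength_labels(self, r, label):
        assert label_correlation_strength(r) == label

    def test_label_out_of_range(self):
        with pytest.raises(ValueError):
            label_correlation_strength(1.2)

    def test_bonferroni_monotone_and_capped(self):
        ps = [0.001, 0.01, 0.2, 0.5]
        adj = [bonferroni(p, 6) for p in ps]
        assert adj == sorted(adj)
        assert adj[-1] == 1.0
        assert adj[0] == pytest.approx(0.006)
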