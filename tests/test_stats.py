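"""Statistical layer: McNemar, trend, group comparisons, screening, models."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps

from ddiscreen.stats import (
    PairedBinary2x2,
    RegressionResult,
    SeparationError,
    TrendSeries,
    build_design_matrix,
    check_collinearity,
    chi2_trend_test,
    compare_groups,
    fit_multivariable,
    mcnemar_test,
    univariate_screen,
)


class TestMcNemar:
    def test_symmetric_discordance_is_null(self):
        stat, p = mcnemar_test(PairedBinary2x2(50, 7, 7, 50))
        assert stat == 0.0
        assert p == pytest.approx(1.0)

    def test_exact_p_equals_binomial_tail(self):
        _, p = mcnemar_test(PairedBinary2x2(100, 10, 2, 100), method="exact")
        assert p == pytest.approx(sps.binomtest(2, 12, 0.5).pvalue)

    def test_no_discordant_pairs_warns_p_one(self):
        with pytest.warns(UserWarning, match="discordant"):
            stat, p = mcnemar_test(PairedBinary2x2(30, 0, 0, 70))
        assert (stat, p) == (0.0, 1.0)

    def test_auto_switches_variant_at_25_discordant(self):
        small = PairedBinary2x2(0, 13, 11, 0)
        assert mcnemar_test(small)[1] == pytest.approx(
            mcnemar_test(small, method="exact")[1])
        big = PairedBinary2x2(0, 40, 20, 0)
        assert mcnemar_test(big)[1] == pytest.approx(
            mcnemar_test(big, method="chi2")[1])


class TestTrend:
    def test_constant_proportions_are_null(self):
        s = TrendSeries((("t1", 50, 500), ("t2", 50, 500),
                         ("t6", 50, 500), ("t12", 50, 500)))
        stat, p = chi2_trend_test(s)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_strong_monotone_trend_is_significant(self):
        s = TrendSeries((("t1", 50, 500), ("t2", 100, 500),
                         ("t6", 150, 500), ("t12", 200, 500)))
        _, p = chi2_trend_test(s)
        assert p < 1e-3

    def test_two_timepoints_reduce_to_pearson_chi2(self):
        s = TrendSeries((("t1", 120, 400), ("t2", 150, 400)))
        stat, p = chi2_trend_test(s)
        table = np.array([[120, 280], [150, 250]])
        ref = sps.chi2_contingency(table, correction=False)
        assert stat == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)

    def test_scaling_counts_scales_statistic_and_shrinks_p(self):
        base = (("t1", 55, 500), ("t2", 60, 500), ("t6", 66, 500), ("t12", 70, 500))
        s1, p1 = chi2_trend_test(TrendSeries(base))
        s4, p4 = chi2_trend_test(
            TrendSeries(tuple((tp, 4 * x, 4 * n) for tp, x, n in base)))
        assert s4 == pytest.approx(4 * s1)
        assert p4 < p1

    def test_degenerate_all_negative(self):
        s = TrendSeries((("t1", 0, 100), ("t2", 0, 100)))
        assert chi2_trend_test(s) == (0.0, 1.0)


class TestCompareGroups:
    def test_identical_samples_null(self):
        x = list(range(30)) * 2
        g = ["a"] * 30 + ["b"] * 30
        assert compare_groups(x, g) == pytest.approx(1.0, abs=0.05)

    def test_extreme_2x2_matches_hypergeometric(self):
        vals = ["yes"] * 10 + ["no"] * 10
        grp = ["a"] * 10 + ["b"] * 10
        p = compare_groups(vals, grp)
        from math import comb
        assert p == pytest.approx(2 / comb(20, 10))
        assert p < 1e-3

    def test_three_shifted_groups_kruskal(self):
        rng = np.random.default_rng(3)
        x = np.concatenate([rng.normal(0, 1, 60), rng.normal(0, 1, 60),
                            rng.normal(5, 1, 60)])
        g = ["a"] * 60 + ["b"] * 60 + ["c"] * 60
        assert compare_groups(x, g) < 1e-3

    def test_single_group_errors(self):
        with pytest.raises(ValueError, match="2 groups"):
            compare_groups([1, 2, 3], ["a", "a", "a"])


class TestUnivariateScreen:
    def test_constant_covariate_skipped(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame({"flat": np.ones(200), "ok": rng.random(200)})
        y = rng.integers(0, 2, 200)
        with pytest.warns(UserWarning, match="single level"):
            out = univariate_screen(X, y)
        row = out.set_index("variable").loc["flat"]
        assert not row["selected"] and "skipped" in row["note"]

    def test_strong_covariate_always_retained(self):
        rng = np.random.default_rng(1)
        for rep in range(10):
            x = rng.random(2000) < 0.3
            logits = -0.5 + np.log(2) * x
            y = rng.random(2000) < 1 / (1 + np.exp(-logits))
            out = univariate_screen(pd.DataFrame({"x": x}), y.astype(float))
            assert out["selected"].all()

    def test_null_covariate_retention_near_alpha(self):
        rng = np.random.default_rng(2)
        kept = 0
        reps = 150
        for _ in range(reps):
            x = rng.random(400) < 0.5
            y = (rng.random(400) < 0.4).astype(float)
            kept += int(univariate_screen(
                pd.DataFrame({"x": x}), y)["selected"].iloc[0])
        # type-I retention should sit near alpha=.15; generous 3-sigma band
        assert kept / reps < 0.15 + 3 * np.sqrt(0.15 * 0.85 / reps)

    def test_degenerate_outcome_errors(self):
        with pytest.raises(ValueError, match="degenerate"):
            univariate_screen(pd.DataFrame({"x": [1.0, 2.0]}), [1.0, 1.0])


class TestCollinearity:
    def test_duplicated_covariate_flagged_at_one(self):
        rng = np.random.default_rng(4)
        x = rng.random(500)
        out = check_collinearity(pd.DataFrame({"a": x, "b": x}))
        assert len(out) == 1
        assert out.iloc[0]["coefficient"] == pytest.approx(1.0)

    def test_threshold_variable_of_itself_flagged(self):
        rng = np.random.default_rng(5)
        drugs = rng.integers(5, 25, 1000)
        df = pd.DataFrame({"drugs_per_day": drugs.astype(float),
                           "hyperpolypharmacy": drugs >= 10})
        out = check_collinearity(df)
        assert len(out) == 1 and out.iloc[0]["kind"] == "point_biserial"

    def test_independent_covariates_not_flagged(self):
        rng = np.random.default_rng(6)
        df = pd.DataFrame({"a": rng.random(2000), "b": rng.random(2000),
                           "c": rng.random(2000) < 0.4})
        assert check_collinearity(df).empty


class TestMultivariableFit:
    def test_single_binary_covariate_matches_cross_product_odds_ratio(self):
        # 2x2: 132 exposed cases, 41 exposed controls, 913/864 unexposed
        x = []
        yy = []
        for exposed, outcome, n in [(1, 1, 132), (1, 0, 41),
                                    (0, 1, 913), (0, 0, 864)]:
            x += [exposed] * n
            yy += [outcome] * n
        df = pd.DataFrame({"depression": np.array(x, dtype=bool)})
        res = fit_multivariable(df, np.array(yy, dtype=float), c_ci=None)
        row = res.table.iloc[0]
        expected = (132 * 864) / (913 * 41)
        assert row["or"] == pytest.approx(expected, rel=1e-4)
        assert expected == pytest.approx(3.05, abs=0.01)
        assert row["ci_low"] <= row["or"] <= row["ci_high"]
        assert res.n == 1950

    def test_orthogonal_covariates_match_univariate_odds_ratios(self):
        rng = np.random.default_rng(7)
        n = 6000
        x1 = rng.random(n) < 0.5
        x2 = rng.random(n) < 0.5  # independent, null effect
        logits = -0.3 + 0.8 * x1
        y = (rng.random(n) < 1 / (1 + np.exp(-logits))).astype(float)
        multi = fit_multivariable(pd.DataFrame({"x1": x1, "x2": x2}), y, c_ci=None)
        uni = fit_multivariable(pd.DataFrame({"x1": x1}), y, c_ci=None)
        b_multi = multi.table.set_index("variable").loc["x1", "coef"]
        b_uni = uni.table.set_index("variable").loc["x1", "coef"]
        assert b_multi == pytest.approx(b_uni, abs=0.05)

    def test_perfect_separation_raises(self):
        x = np.array([0] * 50 + [1] * 50)
        y = x.astype(float)
        with pytest.raises((SeparationError, RuntimeError)):
            fit_multivariable(pd.DataFrame({"x": x.astype(bool)}), y, c_ci=None)

    def test_c_statistic_bootstrap_ci_brackets_estimate(self):
        rng = np.random.default_rng(8)
        x = rng.random(400) < 0.5
        y = (rng.random(400) < np.where(x, 0.7, 0.3)).astype(float)
        res = fit_multivariable(pd.DataFrame({"x": x}), y,
                                c_ci="bootstrap", n_boot=200, seed=1)
        lo, hi = res.c_ci
        assert lo <= res.c_statistic <= hi
        assert 0.5 < res.c_statistic < 1.0

    def test_reference_levels_control_dummy_coding(self):
        df = pd.DataFrame({"site": ["Bern", "Cork", "Utrecht", "Louvain"] * 50})
        X, meta = build_design_matrix(df)
        assert "site[Bern]" not in X.columns  # Bern is the reference
        assert set(meta["level"]) == {"Cork", "Utrecht", "Louvain"}
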