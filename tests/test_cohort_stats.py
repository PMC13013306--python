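"""Contingency statistics, logistic regression, VIF and ICC."""

import numpy as np
import pytest
from scipy import stats as sps

import stasfd as sf
from stasfd.cohort_stats import ContingencyTable2x2, SeparationError, mann_whitney_u

from conftest import (
    TABLE1_COUNTS,
    fisher_enumeration,
    make_table1_cohort,
    mann_whitney_u_bruteforce,
)


class TestCrosstab:
    def test_reference_cohort_counts(self, table1_cohort):
        t = sf.crosstab(table1_cohort["morph_irregularity"], table1_cohort["stas"])
        assert (t.a, t.b, t.c, t.d) == (13, 35, 4, 58)

    def test_all_zero_feature(self):
        t = sf.crosstab([0, 0, 0, 0], [1, 1, 0, 0])
        assert (t.a, t.b, t.c, t.d) == (0, 2, 0, 2)

    def test_feature_identical_to_label(self):
        t = sf.crosstab([1, 1, 0], [1, 1, 0])
        assert (t.a, t.b, t.c, t.d) == (2, 0, 0, 1)

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            sf.crosstab([0, 2], [1, 0])


class TestChi2:
    @pytest.mark.parametrize("cells, yates, expected", [
        ((32, 16, 24, 38), False, 8.461),   # pleural indentation
        ((39, 9, 39, 23), False, 4.415),    # lobulation
        ((13, 35, 4, 58), True, 7.306),     # morphological irregularity
        ((15, 33, 19, 43), False, 0.005),   # sex
        ((11, 37, 10, 52), False, 0.807),   # smoking
    ])
    def test_reference_statistics(self, cells, yates, expected):
        res = sf.pearson_chi2(ContingencyTable2x2(*cells), yates=yates)
        assert res.statistic == pytest.approx(expected, abs=5e-4)
        assert res.df == 1

    def test_proportional_table_is_zero(self):
        assert sf.pearson_chi2(ContingencyTable2x2(10, 20, 10, 20)).statistic == pytest.approx(0.0)

    def test_auto_policy_correction_choice(self):
        # small expected cells -> Yates; comfortable cells -> uncorrected
        assert sf.chi2_auto(ContingencyTable2x2(13, 35, 4, 58)).continuity_corrected
        assert not sf.chi2_auto(ContingencyTable2x2(11, 37, 10, 52)).continuity_corrected

    @pytest.mark.parametrize("seed", range(10))
    def test_symmetry_and_yates_bound(self, seed):
        rng = np.random.default_rng(seed)
        a, b, c, d = rng.integers(1, 40, 4)
        t = ContingencyTable2x2(a, b, c, d)
        swapped_groups = ContingencyTable2x2(b, a, d, c)
        transposed = ContingencyTable2x2(a, c, b, d)
        plain = sf.pearson_chi2(t).statistic
        assert sf.pearson_chi2(swapped_groups).statistic == pytest.approx(plain)
        assert sf.pearson_chi2(transposed).statistic == pytest.approx(plain)
        assert sf.pearson_chi2(t, yates=True).statistic <= plain + 1e-12

    def test_zero_marginal_directs_to_fisher(self):
        with pytest.raises(ValueError, match="[Ff]isher"):
            sf.pearson_chi2(ContingencyTable2x2(0, 0, 5, 5))


class TestFisher:
    def test_extreme_table_closed_form(self):
        from math import comb
        p = sf.fisher_exact(ContingencyTable2x2(10, 0, 0, 10))
        assert p == pytest.approx(2 / comb(20, 10), rel=1e-9)

    def test_balanced_table_is_one(self):
        assert sf.fisher_exact(ContingencyTable2x2(5, 5, 5, 5)) == pytest.approx(1.0)

    @pytest.mark.parametrize("cells", [(1, 9, 9, 1), (3, 7, 2, 8), (0, 5, 6, 4), (4, 4, 4, 4)])
    def test_matches_margin_fixed_enumeration(self, cells):
        assert sf.fisher_exact(ContingencyTable2x2(*cells)) == pytest.approx(
            fisher_enumeration(*cells), rel=1e-9)


class TestOddsRatio:
    @pytest.mark.parametrize("cells, expected_or, expected_ci", [
        ((13, 35, 4, 58), 5.386, (1.628, 17.820)),   # morphological irregularity
        ((32, 16, 24, 38), 3.167, (1.440, 6.965)),   # pleural indentation
        ((39, 9, 39, 23), 2.556, (1.050, 6.219)),    # lobulation
        ((5, 5, 5, 5), 1.0, None),
    ])
    def test_reference_odds_ratios(self, cells, expected_or, expected_ci):
        res = sf.odds_ratio_woolf(ContingencyTable2x2(*cells))
        assert res.odds_ratio == pytest.approx(expected_or, rel=1e-3)
        if expected_ci:
            assert res.ci_low == pytest.approx(expected_ci[0], rel=1e-3)
            assert res.ci_high == pytest.approx(expected_ci[1], rel=1e-3)

    def test_haldane_correction_on_zero_cell(self):
        res = sf.odds_ratio_woolf(ContingencyTable2x2(5, 5, 0, 10))
        assert np.isfinite(res.odds_ratio) and res.ci_low > 0

    def test_zero_row_undefined(self):
        with pytest.raises(ValueError, match="undefined"):
            sf.odds_ratio_woolf(ContingencyTable2x2(0, 5, 0, 5))


class TestGroupCompare:
    def test_identical_groups(self):
        with pytest.warns(UserWarning, match="identical"):
            stat, p = sf.group_compare_continuous([1.0, 1.0, 1.0], [1.0, 1.0], method="t")
        assert (stat, p) == (0.0, 1.0)

    def test_complete_separation_extremes(self):
        x_pos = np.arange(10.0)          # all smaller
        x_neg = np.arange(100.0, 110.0)  # all larger
        assert mann_whitney_u(x_pos, x_neg) == 0.0
        z, p = sf.group_compare_continuous(x_pos, x_neg, method="mann_whitney")
        # |Z| at its maximum for n1 = n2 = 10
        n1 = n2 = 10
        zmax = (n1 * n2 / 2) / np.sqrt(n1 * n2 * (n1 + n2 + 1) / 12)
        assert abs(z) == pytest.approx(zmax)
        assert p < 1e-3

    @pytest.mark.parametrize("seed", range(6))
    def test_u_statistic_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        x1 = rng.integers(0, 8, size=rng.integers(3, 9)).astype(float)
        x2 = rng.integers(0, 8, size=rng.integers(3, 9)).astype(float)
        assert mann_whitney_u(x1, x2) == pytest.approx(mann_whitney_u_bruteforce(x1, x2))

    def test_pooled_t_matches_scipy(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(0, 1, 20), rng.normal(0.5, 1, 25)
        stat, p = sf.group_compare_continuous(a, b, method="t")
        ref = sps.ttest_ind(a, b, equal_var=True)
        assert stat == pytest.approx(ref.statistic) and p == pytest.approx(ref.pvalue)


class TestLogistic:
    def test_binary_predictor_equals_cross_product_or(self, table1_cohort):
        x = table1_cohort[["morph_irregularity"]].to_numpy(dtype=float)
        y = table1_cohort["stas"].to_numpy()
        fit = sf.logistic_fit(x, y, feature_names=["morph_irregularity"])
        assert fit.odds_ratios[0] == pytest.approx(13 * 58 / (35 * 4), abs=1e-6)

    def test_intercept_only_is_logit_prevalence(self):
        y = np.array([1] * 48 + [0] * 62)
        fit = sf.logistic_fit(None, y)
        assert fit.intercept == pytest.approx(np.log(48 / 62), abs=1e-8)

    def test_perfect_separation_raises(self):
        x = np.linspace(-1, 1, 30)[:, None]
        y = (x[:, 0] > 0).astype(int)
        with pytest.raises(SeparationError):
            sf.logistic_fit(x, y)

    def test_constant_predictor_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            sf.logistic_fit(np.ones((30, 1)), np.tile([0, 1], 15))


class TestVif:
    def test_orthogonal_predictors(self):
        # balanced +/-1 design: centered, mutually orthogonal
        X = np.array([[1, 1], [1, -1], [-1, 1], [-1, -1]] * 5, dtype=float)
        out = sf.vif(X)
        assert np.allclose(out["vif"], 1.0)

    def test_duplicated_column_flagged_infinite(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=30)
        out = sf.vif(np.column_stack([x, x, rng.normal(size=30)]))
        assert out["collinear"][:2].all()
        assert np.isinf(out["vif"][:2]).all()

    def test_matches_independent_ols_oracle(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(200, 5))
        X[:, 1] += 0.8 * X[:, 0]
        out = sf.vif(X)
        for i in range(5):
            others = np.delete(X, i, axis=1)
            A = np.column_stack([np.ones(len(X)), others])
            beta, *_ = np.linalg.lstsq(A, X[:, i], rcond=None)
            resid = X[:, i] - A @ beta
            r2 = 1 - resid @ resid / ((X[:, i] - X[:, i].mean()) ** 2).sum()
            assert out["vif"][i] == pytest.approx(1 / (1 - r2), rel=1e-9)


class TestIcc:
    def test_identical_raters(self):
        r = np.tile(np.arange(10.0)[:, None], (1, 2))
        assert sf.icc_agreement(r) == pytest.approx(1.0)

    def test_constant_offset_hurts_agreement_not_consistency(self):
        base = np.arange(10.0)
        r = np.column_stack([base, base + 5.0])
        assert sf.icc_agreement(r, form="consistency") == pytest.approx(1.0)
        assert sf.icc_agreement(r, form="agreement") < 0.9

    def test_simulated_variance_ratio(self):
        rng = np.random.default_rng(3)
        sigma_s, sigma_e = 2.0, 1.0
        subj = rng.normal(0, sigma_s, 4000)
        r = subj[:, None] + rng.normal(0, sigma_e, (4000, 2))
        expected = sigma_s**2 / (sigma_s**2 + sigma_e**2)
        assert sf.icc_agreement(r) == pytest.approx(expected, abs=0.03)

    def test_matches_pingouin(self):
        import pandas as pd
        import pingouin as pg

        rng = np.random.default_rng(4)
        r = rng.normal(0, 1, 20)[:, None] + rng.normal(0, 0.5, (20, 3))
        long = pd.DataFrame({
            "subject": np.repeat(np.arange(20), 3),
            "rater": np.tile(np.arange(3), 20),
            "score": r.ravel(),
        })
        icc = pg.intraclass_corr(long, targets="subject", raters="rater", ratings="score")
        ref21 = float(icc.loc[icc["Type"] == "ICC(A,1)", "ICC"].iloc[0])  # two-way random, agreement
        ref31 = float(icc.loc[icc["Type"] == "ICC(C,1)", "ICC"].iloc[0])  # consistency
        assert sf.icc_agreement(r) == pytest.approx(ref21, abs=1e-9)
        assert sf.icc_agreement(r, form="consistency") == pytest.approx(ref31, abs=1e-9)

    def test_zero_between_subject_variance(self):
        with pytest.raises(ValueError, match="between-subject"):
            sf.icc_agreement(np.column_stack([np.ones(6), np.zeros(6)]))


class TestReports:
    def test_table1_report_reproduces_reference_rows(self, table1_cohort):
        t1 = sf.table1_report(table1_cohort)
        row = t1.set_index("feature")
        assert row.loc["morph_irregularity", "statistic"] == pytest.approx(7.306, abs=5e-4)
        assert row.loc["morph_irregularity", "test"] == "chi2_yates"
        assert row.loc["lobulation", "statistic"] == pytest.approx(4.415, abs=5e-4)
        assert row.loc["lobulation", "test"] == "chi2"
        assert row.loc["pleural_indentation", "statistic"] == pytest.approx(8.461, abs=5e-4)
        assert row.loc["smoking", "statistic"] == pytest.approx(0.807, abs=5e-4)
        assert row.loc["smoking", "test"] == "chi2"

    def test_table2_univariate_matches_woolf(self, table1_cohort):
        t2 = sf.table2_report(table1_cohort)
        uni = t2["univariate"].set_index("feature")
        assert uni.loc["morph_irregularity", "odds_ratio"] == pytest.approx(5.386, rel=1e-3)
        assert uni.loc["pleural_indentation", "odds_ratio"] == pytest.approx(3.167, rel=1e-3)

    def test_validate_cohort_lists_all_problems(self, table1_cohort):
        bad = table1_cohort.copy()
        bad = bad.drop(columns=["fd3d"])
        bad.loc[0, "sex"] = 2
        bad.loc[1, "patient_id"] = bad.loc[2, "patient_id"]
        with pytest.raises(ValueError) as exc:
            sf.cohort_stats.validate_cohort(bad)
        msg = str(exc.value)
        assert "fd3d" in msg and "sex" in msg and "duplicate" in msg
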