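"""Group comparisons, BP adjustment, imputation, pooling and correlations."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from bametrics.cohort_sim import CohortSimSpec, simulate_cohort
from bametrics.stats import (MODEL1_X_COVARIATES, MODEL1_Y_COVARIATES,
                             MODEL2_EXTRA, adjust_bp, apply_bp_adjustment,
                             chi_square_from_counts, compare_groups,
                             fit_group_models, impute, model1_model2_suite,
                             partial_spearman, percent_effect,
                             percent_to_beta, pool_rubin)


@pytest.fixture(scope="module")
def cohort():
    table, truth = simulate_cohort(CohortSimSpec(seed=7))
    return table


@pytest.fixture(scope="module")
def complete_cohort():
    table, truth = simulate_cohort(CohortSimSpec(seed=7, missingness={}))
    return table


# ---------------------------------------------------------------------------
# blood-pressure adjustment
# ---------------------------------------------------------------------------

class TestAdjustBP:
    def test_treated_untreated_and_missing(self):
        assert adjust_bp(152, 84, True) == (162, 89)
        assert adjust_bp(143, 81, False) == (143, 81)
        s, d = adjust_bp(np.nan, 81, True)
        assert np.isnan(s) and d == 86

    def test_table_level_adjustment(self, cohort):
        adj = apply_bp_adjustment(cohort)
        treated = cohort["antihypertensive"] == 1
        delta_s = adj.loc[treated, "sbp_mmhg"] - cohort.loc[treated, "sbp_mmhg"]
        assert np.all(np.isclose(delta_s, 10) | delta_s.isna())
        untreated = ~treated
        assert adj.loc[untreated, "dbp_mmhg"].equals(
            cohort.loc[untreated, "dbp_mmhg"])


# ---------------------------------------------------------------------------
# group comparisons
# ---------------------------------------------------------------------------

class TestCompareGroups:
    def test_chi_square_matches_brute_force(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            counts = rng.integers(5, 80, size=(3, 3)).astype(float)
            stat, dof, p = chi_square_from_counts(counts)
            expected = counts.sum(1, keepdims=True) * \
                counts.sum(0, keepdims=True) / counts.sum()
            brute = np.sum((counts - expected) ** 2 / expected)
            assert stat == pytest.approx(brute, rel=1e-12)
            assert dof == (counts.shape[0] - 1) * (counts.shape[1] - 1)

    def test_published_diabetes_table(self):
        counts = np.array([[16, 35, 29], [104, 85, 91]])
        stat, dof, p = chi_square_from_counts(counts)
        assert dof == 2
        assert p == pytest.approx(0.011, abs=5e-4)

    def test_published_female_counts_highly_significant(self):
        counts = np.array([[41, 53, 79], [79, 67, 41]])
        _, _, p = chi_square_from_counts(counts)
        assert p < 0.0005

    def test_identical_groups_give_zero_statistic(self):
        df = pd.DataFrame({"ethnicity": ["EU"] * 20 + ["SA"] * 20 + ["AC"] * 20,
                           "flag": [0, 1] * 30})
        res = compare_groups(df, "flag", "categorical")
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)
        assert res.pairwise is None  # omnibus not significant: no post hoc

    def test_pairwise_only_when_omnibus_significant(self, complete_cohort):
        res = compare_groups(complete_cohort, "height_cm", "continuous")
        if res.p < 0.05:
            assert set(res.pairwise) == {("EU", "SA"), ("EU", "AC"),
                                         ("SA", "AC")}
        res2 = compare_groups(complete_cohort, "ba_length_mm",
                              "adjusted-imaging",
                              adjusters=["age_years", "female", "height_cm"])
        assert 0 <= res2.p <= 1

    def test_continuous_anova_matches_scipy(self, complete_cohort):
        res = compare_groups(complete_cohort, "age_years", "continuous")
        arrays = [g["age_years"].to_numpy()
                  for _, g in complete_cohort.groupby("ethnicity")]
        ref = sps.f_oneway(*arrays)
        assert res.statistic == pytest.approx(ref.statistic)
        assert res.p == pytest.approx(ref.pvalue)


# ---------------------------------------------------------------------------
# imputation
# ---------------------------------------------------------------------------

class TestImpute:
    def test_complete_table_passes_through(self, complete_cohort):
        imp = impute(complete_cohort, m=3, seed=0)
        for t in imp.tables:
            pd.testing.assert_frame_equal(t, complete_cohort)

    def test_same_seed_identical_different_seed_not(self, cohort):
        a = impute(cohort, m=3, seed=5)
        b = impute(cohort, m=3, seed=5)
        for ta, tb in zip(a.tables, b.tables):
            pd.testing.assert_frame_equal(ta, tb)
        c = impute(cohort, m=3, seed=6)
        assert not a.tables[0].equals(c.tables[0])

    def test_observed_values_never_altered(self, cohort):
        imp = impute(cohort, m=2, seed=1)
        for col in imp.imputed_columns:
            obs = ~cohort[col].isna()
            for t in imp.tables:
                assert np.allclose(t.loc[obs, col], cohort.loc[obs, col])

    def test_imputed_values_fill_all_missing(self, cohort):
        imp = impute(cohort, m=2, seed=1)
        for t in imp.tables:
            assert not t[imp.imputed_columns].isna().any().any()

    def test_pooled_mean_close_to_complete_data_mean(self):
        # MAR missingness on cholesterol: the PMM-imputed mean tracks the
        # complete-data mean within Monte-Carlo tolerance
        diffs = []
        for seed in range(10):
            spec = CohortSimSpec(seed=seed, missingness={
                "total_cholesterol_mmol_l": 0.10})
            table, _ = simulate_cohort(spec)
            complete, _ = simulate_cohort(
                CohortSimSpec(seed=seed, missingness={}))
            imp = impute(table, m=10, seed=seed)
            pooled = np.mean([t["total_cholesterol_mmol_l"].mean()
                              for t in imp.tables])
            diffs.append(pooled - complete["total_cholesterol_mmol_l"].mean())
        se = np.std(diffs) / np.sqrt(len(diffs))
        assert abs(np.mean(diffs)) < 2 * max(se, 0.02)

    def test_all_missing_column_rejected(self, cohort):
        bad = cohort.copy()
        bad["hdl_mmol_l"] = np.nan
        with pytest.raises(ValueError, match="entirely missing"):
            impute(bad, m=2, seed=0)

    def test_missingness_cap_enforced(self, cohort):
        bad = cohort.copy()
        bad.loc[bad.sample(frac=0.6, random_state=0).index,
                "hdl_mmol_l"] = np.nan
        with pytest.raises(ValueError, match="cap"):
            impute(bad, m=2, seed=0)


# ---------------------------------------------------------------------------
# Rubin pooling
# ---------------------------------------------------------------------------

class TestRubinPooling:
    def test_m1_equals_single_fit(self, complete_cohort):
        import statsmodels.formula.api as smf

        sub = complete_cohort[complete_cohort["ethnicity"] == "SA"]
        fit = smf.ols("ba_diameter_mm ~ age_years + female", data=sub).fit()
        pooled = pool_rubin(fit.params.to_numpy()[None, :],
                            (fit.bse.to_numpy() ** 2)[None, :],
                            df_complete=fit.df_resid)
        assert np.allclose(pooled["estimate"], fit.params)
        assert np.allclose(pooled["se"], fit.bse)
        assert np.allclose(pooled["p"], fit.pvalues, atol=1e-12)
        ci = fit.conf_int()
        assert np.allclose(pooled["ci_low"], ci[0])
        assert np.allclose(pooled["ci_high"], ci[1])

    def test_between_variance_widens_interval(self):
        est = np.array([[1.0], [1.4], [0.6]])
        var = np.full((3, 1), 0.04)
        pooled = pool_rubin(est, var, df_complete=100)
        assert pooled["se"].iloc[0] > 0.2
        assert pooled["ci_low"].iloc[0] < pooled["estimate"].iloc[0] \
            < pooled["ci_high"].iloc[0]

    def test_regression_on_complete_data_invariant_to_imputation_seed(
            self, complete_cohort):
        r1 = fit_group_models(impute(complete_cohort, m=3, seed=1),
                              "ba_diameter_mm", group="SA")
        r2 = fit_group_models(impute(complete_cohort, m=3, seed=99),
                              "ba_diameter_mm", group="SA")
        pd.testing.assert_frame_equal(r1.table, r2.table)


# ---------------------------------------------------------------------------
# regression reports
# ---------------------------------------------------------------------------

class TestGroupModels:
    def test_report_shape_and_effect_size_sign(self, cohort):
        imp = impute(cohort, m=3, seed=0)
        rep = fit_group_models(imp, "ba_diameter_mm", group="SA")
        t = rep.table
        assert {"estimate", "ci_low", "ci_high", "p", "cohen_d"} <= set(t.columns)
        assert (t["ci_low"] <= t["estimate"]).all()
        assert (t["estimate"] <= t["ci_high"]).all()
        nonzero = t["estimate"].abs() > 1e-12
        assert np.all(np.sign(t.loc[nonzero, "cohen_d"])
                      == np.sign(t.loc[nonzero, "estimate"]))

    def test_log_outcome_reports_percent_effects(self, cohort):
        imp = impute(cohort, m=3, seed=0)
        rep = fit_group_models(imp, "wmh_total_ml", group="EU")
        assert rep.log_scale
        t = rep.table
        assert np.allclose(t["percent_per_unit"],
                           100 * (np.exp(t["estimate"]) - 1))

    def test_known_log_beta_maps_to_percent(self):
        # a log-scale slope of 0.0840 per year reads as +8.76% per year
        assert percent_effect(0.0840) == pytest.approx(8.76, abs=0.01)

    def test_duplicated_covariate_rejected(self, complete_cohort):
        imp = impute(complete_cohort, m=1, seed=0)
        dup = [t.assign(age_copy=t["age_years"]) for t in imp.tables]
        imp.tables = dup
        with pytest.raises(ValueError, match="collinear"):
            fit_group_models(imp, "ba_diameter_mm",
                             covariates=["age_years", "age_copy"], group="SA")


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.floats(min_value=-0.5, max_value=0.5))
def test_percent_effect_round_trip(beta):
    assert percent_to_beta(percent_effect(beta)) == pytest.approx(beta,
                                                                  abs=1e-12)


# ---------------------------------------------------------------------------
# partial Spearman
# ---------------------------------------------------------------------------

class TestPartialSpearman:
    def test_no_covariates_equals_plain_spearman(self, complete_cohort):
        imp = impute(complete_cohort, m=1, seed=0)
        res = partial_spearman(imp, "ba_length_mm", "wmh_total_ml", group="SA")
        sub = complete_cohort[complete_cohort["ethnicity"] == "SA"]
        ref = sps.spearmanr(sub["ba_length_mm"], sub["wmh_total_ml"])
        assert res.rho == pytest.approx(ref.statistic, abs=1e-9)

    def test_rank_then_pearson_oracle(self, complete_cohort):
        imp = impute(complete_cohort, m=1, seed=0)
        res = partial_spearman(imp, "ba_diameter_mm", "wmh_frontal_ml",
                               group="EU")
        sub = complete_cohort[complete_cohort["ethnicity"] == "EU"]
        rx = sps.rankdata(sub["ba_diameter_mm"])
        ry = sps.rankdata(sub["wmh_frontal_ml"])
        assert res.rho == pytest.approx(np.corrcoef(rx, ry)[0, 1], abs=1e-9)

    def test_perfect_monotone_association(self, complete_cohort):
        imp = impute(complete_cohort, m=1, seed=0)
        mono = [t.assign(wmh_total_ml=np.exp(t["ba_length_mm"] / 10))
                for t in imp.tables]
        imp.tables = mono
        res = partial_spearman(imp, "ba_length_mm", "wmh_total_ml", group="SA")
        assert res.rho_pct == pytest.approx(100.0, abs=1e-6)

    def test_constant_variable_rejected(self, complete_cohort):
        imp = impute(complete_cohort, m=1, seed=0)
        imp.tables = [t.assign(ba_length_mm=47.0) for t in imp.tables]
        with pytest.raises(ValueError, match="constant"):
            partial_spearman(imp, "ba_length_mm", "wmh_total_ml", group="SA")

    def test_confounder_adjustment_removes_spurious_association(self):
        # x and y both driven by age only: raw Spearman is inflated, the
        # age-adjusted partial Spearman is near zero
        raw, adj = [], []
        for seed in range(20):
            spec = CohortSimSpec(seed=seed, missingness={}, group_effects={
                "SA": {"ba_length_mm": {"age_years": 0.6},
                       "wmh_total_ml": {"age_years": 0.12}}},
                residual_sd={"ba_length_mm": 3.0, "wmh_total_ml": 0.6})
            table, _ = simulate_cohort(spec)
            imp = impute(table, m=1, seed=seed)
            raw.append(partial_spearman(imp, "ba_length_mm", "wmh_total_ml",
                                        group="SA").rho)
            adj.append(partial_spearman(imp, "ba_length_mm", "wmh_total_ml",
                                        covariates=["age_years"],
                                        group="SA").rho)
        assert np.mean(raw) > 0.3
        assert abs(np.mean(adj)) < 0.05


class TestModelSuite:
    def test_twelve_rows_per_group(self, cohort):
        imp = impute(cohort, m=2, seed=0)
        suite = model1_model2_suite(imp, "SA")
        assert len(suite) == 12
        assert set(suite["model"]) == {1, 2}
        assert suite.groupby(["x", "y"]).size().eq(2).all()

    def test_model1_covariate_sets(self):
        assert set(MODEL1_X_COVARIATES) == {"age_years", "female",
                                            "height_cm", "cow_variant"}
        assert set(MODEL1_Y_COVARIATES) == {"age_years", "female", "tiv_ml"}

    def test_model2_contains_model1(self):
        m2x = set(MODEL1_X_COVARIATES) | set(MODEL2_EXTRA)
        assert set(MODEL1_X_COVARIATES) <= m2x
        assert len(set(MODEL2_EXTRA) & set(MODEL1_X_COVARIATES)) == 0
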