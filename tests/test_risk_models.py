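"""Outcome transformations, mixed models, ICC, and diagnostics."""

import numpy as np
import pandas as pd
import pytest

from roamrange import (
    compute_icc, fit_mixed_model, influence_assessment, prepare_outcomes,
    simulate_analysis_table, unconditional_tests,
)


def base_table(seed=0, n=73):
    rng = np.random.default_rng(seed)
    t = simulate_analysis_table(seed=seed, n_dogs=n)
    t["daily_distance_km"] = rng.normal(13.0, 4.0, n).clip(1.0)
    t["core_hr_ha"] = rng.lognormal(-1.0, 0.7, n)
    t["extended_hr_ha"] = rng.lognormal(2.2, 0.8, n)
    t["pct_time_household"] = rng.uniform(1.0, 80.0, n)
    t["age_class"] = np.where(t["age_ge1"] == 1, "1-5 yr", "<1 yr")
    t["reported_time_outside"] = rng.choice(["<2 h", "2-6 h", ">6 h"], n)
    t["recording_hours"] = rng.uniform(25.0, 152.0, n)
    return t


class TestPrepareOutcomes:
    def test_transforms(self):
        t = base_table()
        t.loc[0, "core_hr_ha"] = 0.25
        out = prepare_outcomes(t)
        assert out.loc[0, "sqrt_core_hr"] == pytest.approx(0.5)
        assert np.allclose(out["log_extended_hr"], np.log(out["extended_hr_ha"]))

    def test_nonpositive_extended_hr_rejected(self):
        t = base_table()
        t.loc[0, "extended_hr_ha"] = 0.0
        with pytest.raises(ValueError, match="log"):
            prepare_outcomes(t)

    def test_independent_outcomes_not_flagged(self):
        out = prepare_outcomes(base_table(seed=3))
        assert out.attrs["collinear_pairs"] == []

    def test_duplicated_outcome_flagged(self):
        t = base_table()
        t["extended_hr_ha"] = t["core_hr_ha"] + 1.0  # r = 1, stays positive
        out = prepare_outcomes(t)
        pairs = out.attrs["collinear_pairs"]
        assert any({a, b} == {"core_hr_ha", "extended_hr_ha"} for a, b, _ in pairs)
        assert pairs[0][2] == pytest.approx(1.0)


class TestMixedModel:
    def test_strong_effect_recovered(self):
        t = prepare_outcomes(base_table())
        t["daily_distance_km"] = (
            13.0 + 3.0 * t["age_ge1"] + np.random.default_rng(1).normal(0, 1.0, len(t))
        )
        fit = fit_mixed_model(t, "daily_distance_km", ("age_ge1", "sex_status"))
        assert fit.coefficients["age_ge1"] == pytest.approx(3.0, abs=1.5)
        assert fit.term_p_values["age_ge1"] < 0.001
        assert "age_ge1" in fit.significant_terms

    def test_outcome_transform_dispatch(self):
        t = prepare_outcomes(base_table())
        fit = fit_mixed_model(t, "core_hr_ha", ("age_ge1",))
        assert fit.outcome == "core_hr_ha"
        # fitted on the sqrt scale
        ols = np.polyfit(t["age_ge1"], t["sqrt_core_hr"], 1)
        assert fit.coefficients["age_ge1"] == pytest.approx(ols[0], abs=0.2)

    def test_single_site_falls_back_to_ols(self):
        t = prepare_outcomes(base_table())
        t["site"] = "only"
        with pytest.warns(UserWarning, match="ordinary least squares"):
            fit = fit_mixed_model(t, "daily_distance_km", ("age_ge1",))
        assert fit.used_ols_fallback
        assert fit.sigma2_between == 0.0

    def test_zero_between_variance_matches_ols(self):
        # no site effect by construction: mixed fit collapses to OLS
        t = prepare_outcomes(base_table(seed=11))
        fit = fit_mixed_model(t, "daily_distance_km", ("age_ge1", "fixes_per_hour"))
        import statsmodels.formula.api as smf

        ols = smf.ols("daily_distance_km ~ age_ge1 + fixes_per_hour", data=t).fit()
        if fit.sigma2_between == 0.0:
            assert np.allclose(
                fit.coefficients[ols.params.index], ols.params, atol=1e-6
            )
        else:  # tiny spurious variance still keeps estimates very close
            assert np.allclose(
                fit.coefficients[ols.params.index], ols.params, atol=1e-2
            )


class TestICC:
    def test_equal_components_half(self):
        fit = fit_mixed_model(prepare_outcomes(base_table()), "daily_distance_km",
                              ("age_ge1",))
        fit.sigma2_between = 2.0
        fit.sigma2_within = 2.0
        assert compute_icc(fit) == pytest.approx(0.5)

    def test_zero_between_is_zero(self):
        fit = fit_mixed_model(prepare_outcomes(base_table()), "daily_distance_km",
                              ("age_ge1",))
        fit.sigma2_between = 0.0
        fit.sigma2_within = 3.0
        assert compute_icc(fit) == 0.0

    def test_both_zero_flagged_nan(self):
        fit = fit_mixed_model(prepare_outcomes(base_table()), "daily_distance_km",
                              ("age_ge1",))
        fit.sigma2_between = 0.0
        fit.sigma2_within = 0.0
        assert np.isnan(compute_icc(fit))

    def test_monotone_in_between_variance(self):
        fit = fit_mixed_model(prepare_outcomes(base_table()), "daily_distance_km",
                              ("age_ge1",))
        fit.sigma2_within = 1.0
        vals = []
        for s2b in (0.0, 0.5, 1.0, 4.0):
            fit.sigma2_between = s2b
            vals.append(compute_icc(fit))
        assert all(a < b for a, b in zip(vals, vals[1:]))
        assert all(0.0 <= v <= 1.0 for v in vals)


class TestUnconditional:
    def test_constant_covariate_excluded(self):
        t = prepare_outcomes(base_table())
        t["purpose"] = "security"
        res = unconditional_tests(t, covariates=("purpose", "age_class"))
        status = res.loc[res["covariate"] == "purpose", "status"]
        assert (status == "excluded (lack of variation)").all()

    def test_strong_simulated_effect_detected(self):
        t = prepare_outcomes(base_table())
        rng = np.random.default_rng(2)
        t["daily_distance_km"] = 5.0 + 0.5 * t["fixes_per_hour"] + rng.normal(0, 0.5, len(t))
        res = unconditional_tests(t, covariates=("fixes_per_hour",))
        p = res.loc[(res["covariate"] == "fixes_per_hour")
                    & (res["outcome"] == "daily_distance_km"), "p_value"]
        assert float(p.iloc[0]) < 0.001

    def test_categorical_levels_summarised(self):
        t = prepare_outcomes(base_table())
        res = unconditional_tests(t, covariates=("sex_status",))
        summ = res[res["status"] == "summary"]
        assert set(summ["level"]) <= {"intact male", "castrated male",
                                      "intact female", "spayed female"}
        assert "daily_distance_km_median" in summ.columns

    def test_null_pvalues_roughly_uniform(self):
        # covariate independent of outcome: p ~ U(0,1) across replicates
        from scipy import stats

        pvals = []
        for seed in range(40):
            t = prepare_outcomes(base_table(seed=200 + seed))
            res = unconditional_tests(t, covariates=("recording_hours",),
                                      outcomes=("daily_distance_km",))
            pvals.append(float(res["p_value"].iloc[0]))
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestInfluence:
    def test_leave_one_site_out_shape_and_stability(self):
        t = prepare_outcomes(base_table())
        rng = np.random.default_rng(5)
        t["daily_distance_km"] = 10.0 + 4.0 * t["age_ge1"] + rng.normal(0, 1.0, len(t))
        rep = influence_assessment(t, "daily_distance_km", ("age_ge1",))
        assert rep.leave_one_site_out["left_out_site"].nunique() == 8
        assert "age_ge1" in rep.sign_stable_terms

    def test_planted_outlier_flagged(self):
        t = prepare_outcomes(base_table())
        rng = np.random.default_rng(6)
        t["daily_distance_km"] = 13.0 + rng.normal(0, 1.0, len(t))
        t.loc[10, "daily_distance_km"] = 60.0
        rep = influence_assessment(t, "daily_distance_km", ("age_ge1",))
        assert t.loc[10, "dog_id"] in rep.outlier_dogs
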