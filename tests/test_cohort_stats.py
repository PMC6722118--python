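"""Exclusion rules, transforms, and the crossed random-intercept REML fit."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from mosaicquant.cohort_stats import (
    ModelSpec,
    apply_exclusions,
    build_design,
    compute_residuals,
    default_model_suite,
    fit_mixed_model,
    run_model_suite,
    tidy_fits,
    transform_variables,
)
from mosaicquant.errors import SpecValidationError
from mosaicquant.synthetic_data import CohortSpec, generate_cohort, plant_exclusions


def _prepared(spec: CohortSpec, noise_sign=1) -> pd.DataFrame:
    return transform_variables(generate_cohort(spec, noise_sign=noise_sign),
                               percent_col="true_percent")


class TestExclusions:
    def _cohort(self, ages, sexes=None):
        n = len(ages)
        return pd.DataFrame(
            {
                "core_id": [f"c{i}" for i in range(n)],
                "subject_id": [f"s{i}" for i in range(n)],
                "age": ages,
                "sex": sexes if sexes is not None else ["male"] * n,
                "unevaluable": [False] * n,
            }
        )

    def test_age_threshold_is_18(self):
        out, log = apply_exclusions(self._cohort([17.0, 18.0, 40.0]))
        assert len(out) == 2
        assert log.n_under18_rows == 1
        assert log.consistent()

    def test_missing_sex_removed_and_logged(self):
        out, log = apply_exclusions(self._cohort([30, 40], [np.nan, "female"]))
        assert len(out) == 1
        assert log.n_missing_or_unevaluable_rows == 1

    def test_unevaluable_flag_removed(self):
        df = self._cohort([30, 40, 50])
        df.loc[1, "unevaluable"] = True
        out, log = apply_exclusions(df)
        assert len(out) == 2
        assert log.n_missing_or_unevaluable_rows == 1

    def test_planted_counts_recovered(self):
        cohort = generate_cohort(CohortSpec(n_subjects=300, seed=17))
        planted = plant_exclusions(cohort, 8, 23, seed=5)
        _, log = apply_exclusions(planted)
        assert log.n_under18_subjects == 8
        assert log.n_missing_or_unevaluable_rows == 23
        assert log.consistent()

    def test_counts_always_conserve(self, rng):
        for _ in range(5):
            cohort = generate_cohort(CohortSpec(n_subjects=50,
                                                seed=int(rng.integers(1e6))))
            planted = plant_exclusions(cohort, 3, 5, seed=int(rng.integers(1e6)))
            _, log = apply_exclusions(planted)
            assert log.consistent()


class TestTransforms:
    def test_sqrt_fraction_values(self):
        df = pd.DataFrame({"percent_positive": [25.0, 0.0, 100.0]})
        out = transform_variables(df)
        assert out["sqrt_fraction"].tolist() == [0.5, 0.0, 1.0]

    def test_log_transforms(self):
        df = pd.DataFrame({"percent_positive": [10.0], "heart_weight": [403.0],
                           "bmi": [25.0]})
        out = transform_variables(df)
        assert out["log_heart_weight"].iloc[0] == pytest.approx(np.log(403.0))
        assert out["log_heart_weight"].iloc[0] == pytest.approx(5.999, abs=1e-3)
        assert out["log_bmi"].iloc[0] == pytest.approx(np.log(25.0))

    def test_round_trip(self, rng):
        pct = rng.uniform(0, 100, 50)
        out = transform_variables(pd.DataFrame({"percent_positive": pct}))
        assert np.allclose(out["sqrt_fraction"] ** 2 * 100.0, pct, atol=1e-10)

    def test_negative_percent_rejected(self):
        with pytest.raises(SpecValidationError):
            transform_variables(pd.DataFrame({"percent_positive": [-1.0]}))

    def test_missing_propagates(self):
        df = pd.DataFrame({"percent_positive": [np.nan], "heart_weight": [np.nan]})
        out = transform_variables(df)
        assert out["sqrt_fraction"].isna().all()
        assert out["log_heart_weight"].isna().all()


class TestDesign:
    def test_sex_coding_female_reference(self):
        df = pd.DataFrame({"sex": ["male", "female"], "age": [50.0, 60.0],
                           "disease": ["Control", "HCM"]})
        X = build_design(df, ("age", "sex", "disease"))
        assert X["Sex"].tolist() == [1.0, 0.0]
        assert "Control" not in X.columns  # treatment contrast, Control ref
        assert X["HCM"].tolist() == [0.0, 1.0]


class TestMixedModel:
    def test_noiseless_cohort_identifies_effects_exactly(self):
        spec = CohortSpec(n_subjects=50, subject_sd=0, tma_sd=0, residual_sd=0,
                          disease_effects_sqrt_scale={}, seed=5)
        fit = fit_mixed_model(_prepared(spec))
        assert fit.estimates["Sex"] == pytest.approx(0.097, abs=1e-6)
        assert fit.estimates["Age"] == pytest.approx(-0.00013, abs=1e-6)
        assert fit.estimates["(Intercept)"] == pytest.approx(0.29, abs=1e-6)

    def test_zero_random_sds_match_ols(self):
        import statsmodels.api as sm

        spec = CohortSpec(n_subjects=200, subject_sd=0, tma_sd=0, residual_sd=0,
                          disease_effects_sqrt_scale={}, seed=5)
        df = _prepared(spec)
        fit = fit_mixed_model(df)
        X = np.column_stack([np.ones(len(df)), df["age"],
                             (df["sex"] == "male").astype(float)])
        ols = sm.OLS(df["sqrt_fraction"], X).fit()
        assert np.allclose(list(fit.estimates.values()), ols.params, atol=1e-6)
        # no random variation was simulated, so fitted components collapse
        for comp, var in fit.variance_components.items():
            assert var == pytest.approx(0.0, abs=1e-10), comp

    def test_t_equals_estimate_over_se(self):
        fit = fit_mixed_model(_prepared(CohortSpec(n_subjects=80, seed=2)))
        for term in fit.estimates:
            assert fit.t_values[term] == pytest.approx(
                fit.estimates[term] / fit.std_errors[term], abs=1e-8)

    def test_single_tma_reports_boundary_variance(self):
        spec = CohortSpec(n_subjects=60, n_tmas=1, disease_effects_sqrt_scale={},
                          seed=3)
        fit = fit_mixed_model(_prepared(spec))
        assert fit.variance_components["tma_id"] == 0.0
        assert any("tma_id" in s and "single level" in s for s in fit.singular)
        assert "subject_id" in fit.variance_components

    def test_agrees_with_statsmodels_crossed_vc(self):
        import statsmodels.formula.api as smf

        spec = CohortSpec(n_subjects=60, n_tmas=3, replicate_core_probability=0.5,
                          disease_effects_sqrt_scale={}, seed=3)
        df = _prepared(spec).assign(male=lambda d: (d.sex == "male").astype(float))
        ours = fit_mixed_model(df)
        sm_fit = smf.mixedlm(
            "sqrt_fraction ~ age + male", data=df, groups=np.ones(len(df)),
            vc_formula={"subject": "0 + C(subject_id)", "tma": "0 + C(tma_id)"},
            re_formula="0",
        ).fit(reml=True)
        ref = {"(Intercept)": sm_fit.fe_params["Intercept"],
               "Age": sm_fit.fe_params["age"], "Sex": sm_fit.fe_params["male"]}
        for term, val in ref.items():
            assert ours.estimates[term] == pytest.approx(val, abs=2e-5)
        assert ours.std_errors["Sex"] == pytest.approx(sm_fit.bse_fe["male"],
                                                       rel=2e-2)

    def test_agrees_with_lme4(self, tmp_path):
        """lme4 is the reference implementation for this model family."""
        spec = CohortSpec(n_subjects=80, n_tmas=4, replicate_core_probability=0.6,
                          disease_effects_sqrt_scale={}, seed=13)
        df = _prepared(spec).assign(male=lambda d: (d.sex == "male").astype(float))
        csv = tmp_path / "cohort.csv"
        df.to_csv(csv, index=False)
        out = tmp_path / "coef.csv"
        script = textwrap.dedent(f"""
            suppressMessages(library(lme4))
            d <- read.csv("{csv}")
            m <- lmer(sqrt_fraction ~ age + male + (1|subject_id) + (1|tma_id),
                      data = d, REML = TRUE)
            fe <- fixef(m)
            se <- sqrt(diag(as.matrix(vcov(m))))
            write.csv(data.frame(term = names(fe), est = fe, se = se),
                      "{out}", row.names = FALSE)
        """)
        subprocess.run(["Rscript", "-e", script], check=True, capture_output=True)
        ref = pd.read_csv(out).set_index("term")
        ours = fit_mixed_model(df)
        assert ours.estimates["(Intercept)"] == pytest.approx(
            ref.loc["(Intercept)", "est"], abs=2e-5)
        assert ours.estimates["Age"] == pytest.approx(ref.loc["age", "est"], abs=2e-6)
        assert ours.estimates["Sex"] == pytest.approx(ref.loc["male", "est"], abs=2e-5)
        assert ours.std_errors["Sex"] == pytest.approx(ref.loc["male", "se"], rel=1e-3)

    def test_satterthwaite_dfs_finite_and_p_reasonable(self):
        df = _prepared(CohortSpec(n_subjects=80, seed=2))
        z_fit = fit_mixed_model(df)
        sat = fit_mixed_model(df, df_method="satterthwaite")
        for term in sat.estimates:
            assert sat.satterthwaite_df[term] > 0
            # t-based p with finite df is at least the z-based p
            assert sat.p_values[term] >= z_fit.p_values[term] - 1e-12


class TestResiduals:
    def test_noiseless_residuals_vanish(self):
        spec = CohortSpec(n_subjects=40, subject_sd=0, tma_sd=0, residual_sd=0,
                          disease_effects_sqrt_scale={}, seed=4)
        res, _ = compute_residuals(_prepared(spec))
        assert np.allclose(res, 0.0, atol=1e-8)

    def test_orthogonal_to_adjusted_covariates(self):
        df = _prepared(CohortSpec(n_subjects=120, seed=6))
        res, fit = compute_residuals(df)
        X = build_design(df.loc[res.index], ("age", "sex"))
        scale = np.abs(X.to_numpy()).sum(axis=0) * np.abs(res).max()
        dots = np.abs(res.to_numpy() @ X.to_numpy())
        assert np.all(dots <= 1e-6 * np.maximum(scale, 1.0))

    def test_planted_disease_shift_recovered_in_residuals(self):
        spec = CohortSpec(n_subjects=400,
                          disease_effects_sqrt_scale={"HCM": 0.21}, seed=7)
        df = _prepared(spec)
        # subject intercepts guard the fit but stay in the residual, so the
        # subject-level disease shift survives for the group comparison
        res, _ = compute_residuals(df, subtract_random=("tma_id",))
        sub = df.loc[res.index]
        shift = res[sub.disease == "HCM"].mean() - res[sub.disease == "Control"].mean()
        assert shift == pytest.approx(0.21, abs=0.05)
        # the fully conditional residual absorbs most of the shift instead
        cond, _ = compute_residuals(df)
        cshift = (cond[sub.disease == "HCM"].mean()
                  - cond[sub.disease == "Control"].mean())
        assert 0.0 < cshift < shift


class TestModelSuite:
    def test_suite_fits_all_four_models(self):
        df = _prepared(CohortSpec(n_subjects=250, seed=8))
        fits, failures = run_model_suite(df)
        assert failures == {}
        assert set(fits) == {"all_tmas_age_sex", "tma12_disease",
                             "heart_weight", "hcm_combined"}
        assert all(f.converged for f in fits.values())

    def test_heart_weight_missing_rows_dropped_and_counted(self):
        df = _prepared(CohortSpec(n_subjects=120, seed=9))
        spec = [m for m in default_model_suite() if m.name == "heart_weight"][0]
        fit = fit_mixed_model(df, spec)
        n_missing = int(df["heart_weight"].isna().sum())
        assert n_missing > 0
        assert fit.n_dropped_rows == n_missing
        assert fit.n_obs == len(df) - n_missing

    def test_hcm_power_at_planted_effect(self, rng):
        """The combined-cohort HCM model detects a 0.21 sqrt-scale shift in
        nearly every replicate at this sample size."""
        hits = 0
        runs = 25
        spec_model = [m for m in default_model_suite()
                      if m.name == "hcm_combined"][0]
        for _ in range(runs):
            spec = CohortSpec(n_subjects=300, seed=int(rng.integers(2**31)))
            fit = fit_mixed_model(_prepared(spec), spec_model)
            hits += (fit.estimates["HCM"] > 0) and (fit.p_values["HCM"] < 0.05)
        assert hits / runs >= 0.9

    def test_tidy_table_shape(self):
        df = _prepared(CohortSpec(n_subjects=100, seed=10))
        fits, _ = run_model_suite(df)
        table = tidy_fits(fits)
        assert {"model", "term", "estimate", "std_error", "t_value",
                "p_value"} <= set(table.columns)
        assert (table.groupby("model")
                .apply(lambda g: (g.term == "(Intercept)").sum(), include_groups=False)
                .eq(1).all())
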