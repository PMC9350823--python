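"""Mixed-model fitting, model comparison, contrasts, EMMs, effect sizes."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

from dosefreq import (
    DoseResponseLMM,
    LmmFit,
    ModelSpec,
    REFERENCE_FIXED_EFFECTS,
    REFERENCE_VARCOMPS,
    VarianceComponents,
    compare_models,
    emm_at_week,
    emm_contrasts,
    fit_lmm,
    generate_lmm_dataset,
    slope_contrasts,
    treatment_effect_size,
    tukey_p,
)

REF_FIT = LmmFit.from_coefficients(REFERENCE_FIXED_EFFECTS)
B = REFERENCE_FIXED_EFFECTS


def studentized_range_sf_normal_limit(q: float, k: int) -> float:
    """Independent oracle: upper tail of the studentized range in its
    normal limit, P(range of k iid N(0,1) > q), by direct integration of
    k * phi(z) * [Phi(z) - Phi(z - q)]^(k-1)."""
    phi, Phi = stats.norm.pdf, stats.norm.cdf
    val, _ = integrate.quad(lambda z: phi(z) * (Phi(z) - Phi(z - q)) ** (k - 1),
                            -10, 10, epsabs=1e-10)
    return 1.0 - k * val


class TestTukey:
    def test_matches_independent_integral(self):
        for t in (0.3, 0.52, 1.5, 2.37, 3.79):
            for k in (2, 3, 5, 8):
                q = abs(t) * np.sqrt(2)
                assert tukey_p(t, k) == pytest.approx(
                    studentized_range_sf_normal_limit(q, k), abs=1e-6)

    def test_printed_worked_examples(self):
        assert tukey_p(-0.52, 5) == pytest.approx(0.99, abs=0.005)
        assert tukey_p(-2.37, 5) == pytest.approx(0.12, abs=0.005)

    def test_zero_statistic(self):
        assert tukey_p(0.0, 5) == 1.0

    def test_k2_reduces_to_two_sided_normal(self):
        for t in (0.1, 0.7, 1.3, 1.96, 2.8, 4.0):
            assert tukey_p(t, 2) == pytest.approx(2 * stats.norm.sf(abs(t)),
                                                  abs=1e-6)

    def test_monotone_in_t_and_k_and_above_unadjusted(self):
        ts = np.linspace(0.1, 4.0, 12)
        ps = [tukey_p(t, 5) for t in ts]
        assert all(a > b for a, b in zip(ps, ps[1:]))
        for t in (0.5, 1.5, 2.5):
            pk = [tukey_p(t, k) for k in (2, 3, 4, 5, 6)]
            assert all(a <= b for a, b in zip(pk, pk[1:]))
            assert pk[0] >= 2 * stats.norm.sf(t) - 1e-12

    def test_invalid_family_size(self):
        with pytest.raises(ValueError):
            tukey_p(1.0, 1)


class TestSlopeContrasts:
    def test_reference_vector_arithmetic(self):
        out = slope_contrasts(REF_FIT).set_index("contrast")["estimate"]
        assert out["2 vs 3"] == pytest.approx(B["week:group[2]"] - B["week:group[3]"])
        assert out["2 vs 3"] == pytest.approx(-1.69e-3, abs=1e-8)
        assert out["1 vs 3"] == pytest.approx(-2.82e-3, abs=1e-12)
        assert len(out) == 10  # no self-contrasts in the family

    def test_additivity(self):
        out = slope_contrasts(REF_FIT).set_index("contrast")["estimate"]
        assert out["1 vs 2"] + out["2 vs 3"] == pytest.approx(out["1 vs 3"])
        assert out["1 vs 2"] + out["2 vs 3"] == pytest.approx(-2.82e-3, abs=1e-12)

    def test_missing_interaction_terms_rejected(self):
        fit = LmmFit.from_coefficients({"week": 0.01})
        with pytest.raises(ValueError, match="week:group"):
            slope_contrasts(fit)

    def test_se_and_p_require_vcov(self):
        out = slope_contrasts(REF_FIT)
        assert out["se"].isna().all()
        assert out["p_adjusted"].isna().all()


class TestEmm:
    def test_week0_differences_equal_group_main_effects(self):
        out = emm_contrasts(REF_FIT, 0).set_index("contrast")["estimate"]
        assert out["1 vs 5+"] == pytest.approx(-B["group[5+]"])
        assert out["1 vs 2"] == pytest.approx(-B["group[2]"])
        assert out["3 vs 4"] == pytest.approx(B["group[3]"] - B["group[4]"])

    def test_week9_differences_add_nine_weeks_of_interaction(self):
        out = emm_contrasts(REF_FIT, 9).set_index("contrast")["estimate"]
        assert out["1 vs 4"] == pytest.approx(
            -(B["group[4]"] + 9 * B["week:group[4]"]))
        assert out["1 vs 4"] == pytest.approx(-5.09e-2, abs=5e-5)

    def test_identical_coefficients_give_zero_difference(self):
        beta = dict(B)
        beta["group[3]"] = beta["group[2]"]
        beta["week:group[3]"] = beta["week:group[2]"]
        fit = LmmFit.from_coefficients(beta)
        out = emm_contrasts(fit, 7).set_index("contrast")["estimate"]
        assert out["2 vs 3"] == pytest.approx(0.0, abs=1e-15)

    def test_extrapolation_warns(self):
        with pytest.warns(UserWarning, match="extrapolation"):
            emm_at_week(REF_FIT, 12)

    def test_emm_uses_covariate_means(self):
        fit = LmmFit.from_coefficients(
            B, covariate_means={"age": 63.0, "total_hours": 6.2, "baseline": 0.33})
        emm = emm_at_week(fit, 0).set_index("group")["emm"]
        # group differences are invariant to the grid means
        ref = emm_contrasts(REF_FIT, 0).set_index("contrast")["estimate"]
        assert emm["1"] - emm["5+"] == pytest.approx(ref["1 vs 5+"])


class TestEffectSize:
    def _fit(self, beta=None, residual_var=1.4e-2):
        return LmmFit(
            beta=pd.Series(beta or B, dtype=float),
            varcomps=VarianceComponents(residual_var=residual_var,
                                        patient_intercept_var=2.2e-3,
                                        patient_slope_var=1.5e-5),
            covariate_means={"age": 63.0, "total_hours": 0.0, "baseline": 0.33})

    def test_zero_slope_group_has_zero_effect(self):
        beta = dict(B)
        beta["week"] = 0.0
        beta["week:group[2]"] = 0.0
        beta["week:total_hours"] = 0.0
        out = treatment_effect_size(self._fit(beta)).set_index("group")
        assert out.loc["2", "d"] == pytest.approx(0.0, abs=1e-15)

    def test_reference_arithmetic_group1(self):
        out = treatment_effect_size(self._fit()).set_index("group")
        expected = 9 * B["week"] / np.sqrt(1.4e-2)
        assert out.loc["1", "d"] == pytest.approx(expected)
        assert out.loc["1", "d"] == pytest.approx(0.70, abs=0.02)

    def test_quadrupled_variance_halves_d(self):
        d1 = treatment_effect_size(self._fit()).set_index("group")["d"]
        d2 = treatment_effect_size(
            self._fit(residual_var=4 * 1.4e-2)).set_index("group")["d"]
        assert np.allclose(d2.to_numpy(), d1.to_numpy() / 2)

    def test_total_sigma_mode_is_larger_standardizer(self):
        fit = self._fit()
        d_res = treatment_effect_size(fit, "residual")["d"].abs()
        d_tot = treatment_effect_size(fit, "total")["d"].abs()
        assert (d_tot <= d_res + 1e-15).all()

    def test_zero_sigma_rejected(self):
        fit = self._fit(residual_var=0.0)
        fit.varcomps = VarianceComponents(residual_var=0.0)
        with pytest.raises(ValueError, match="sigma"):
            treatment_effect_size(fit)


class TestFitLmm:
    def test_near_noiseless_identifiability(self):
        table = generate_lmm_dataset(
            varcomps=VarianceComponents(residual_var=1e-16),
            group_sizes=(6,) * 5, n_domains=2, n_weeks=10, rng_seed=2)
        fit = fit_lmm(table)
        for term, truth in REFERENCE_FIXED_EFFECTS.items():
            if term in fit.beta.index:
                assert fit.beta[term] == pytest.approx(truth, abs=1e-4), term

    def test_constant_outcome_degenerates(self):
        table = generate_lmm_dataset(
            varcomps=VarianceComponents(residual_var=1e-16),
            group_sizes=(6,) * 5, n_domains=1, n_weeks=10, rng_seed=3)
        table["score"] = 0.5
        fit = fit_lmm(table)
        for term in fit.beta.index:
            if term.startswith("week"):
                assert fit.beta[term] == pytest.approx(0.0, abs=1e-6)
        assert fit.varcomps.residual_var == pytest.approx(0.0, abs=1e-6)

    def test_interaction_recovery_within_two_se(self):
        table = generate_lmm_dataset(group_sizes=(40,) * 5, n_domains=3,
                                     n_weeks=10, rng_seed=12)
        fit = fit_lmm(table)
        for term in ("week:group[2]", "week:group[3]", "week:group[4]",
                     "week:group[5+]"):
            se = np.sqrt(fit.vcov.loc[term, term])
            assert abs(fit.beta[term] - REFERENCE_FIXED_EFFECTS[term]) < 2 * se

    def test_empty_and_single_group_rejected(self):
        table = generate_lmm_dataset(group_sizes=(5, 0, 0, 0, 0), rng_seed=0)
        with pytest.raises(ValueError, match="group"):
            fit_lmm(table)
        with pytest.raises(ValueError, match="empty"):
            fit_lmm(table.iloc[:0])

    def test_collinear_design_names_columns(self):
        table = generate_lmm_dataset(group_sizes=(4, 4, 0, 0, 0),
                                     n_domains=1, rng_seed=1)
        table["age"] = 60.0  # constant -> collinear with intercept
        with pytest.raises(ValueError, match="age"):
            fit_lmm(table)


class TestCompareModels:
    def _mlfit(self, terms, loglik, n_params, n_obs=100):
        return LmmFit(beta=pd.Series(0.0, index=terms), loglik=loglik,
                      n_params=n_params, n_obs=n_obs, method="ml")

    def test_identical_models(self):
        f = self._mlfit(["a", "b"], -50.0, 4)
        res = compare_models(f, f)
        assert res["lrt"] == 0.0 and res["p"] == 1.0
        assert res["delta_aic"] == 0.0

    def test_one_free_parameter_with_no_gain_costs_two_aic(self):
        f0 = self._mlfit(["a"], -50.0, 3)
        f1 = self._mlfit(["a", "b"], -50.0, 4)
        res = compare_models(f0, f1)
        assert res["delta_aic"] == pytest.approx(2.0)
        assert res["delta_bic"] == pytest.approx(np.log(100))

    def test_non_nested_rejected(self):
        f0 = self._mlfit(["a", "c"], -50.0, 4)
        f1 = self._mlfit(["a", "b"], -49.0, 4)
        with pytest.raises(ValueError, match="nested"):
            compare_models(f0, f1)

    def test_reml_fixed_effect_comparison_rejected(self):
        f0 = self._mlfit(["a"], -50.0, 3)
        f1 = self._mlfit(["a", "b"], -49.0, 4)
        f0.method = "reml"
        with pytest.raises(ValueError, match="ML"):
            compare_models(f0, f1)

    def test_lrt_on_real_nested_fits(self):
        table = generate_lmm_dataset(group_sizes=(6,) * 5, n_domains=1,
                                     n_weeks=10, rng_seed=8)
        null = fit_lmm(table, ModelSpec(method="ml", include_group_interaction=False))
        alt = fit_lmm(table, ModelSpec(method="ml"))
        res = compare_models(null, alt)
        assert res["df"] == 4
        assert res["lrt"] >= -1e-6
        assert 0.0 <= res["p"] <= 1.0


class TestDoseResponseEstimator:
    def test_fitted_attributes_and_predict(self):
        table = generate_lmm_dataset(group_sizes=(5,) * 5, n_domains=1,
                                     n_weeks=8, rng_seed=4)
        est = DoseResponseLMM().fit(table)
        assert hasattr(est, "beta_") and hasattr(est, "varcomps_")
        pred = est.predict(table)
        assert pred.shape == (len(table),)
        # fixed-effect predictions correlate strongly with scores
        assert np.corrcoef(pred, table["score"])[0, 1] > 0.5

    def test_sklearn_clone_compatible(self):
        from sklearn.base import clone
        est = DoseResponseLMM(method="ml")
        cloned = clone(est)
        assert cloned.get_params() == est.get_params()

    def test_predict_before_fit_rejected(self):
        with pytest.raises(ValueError, match="not fitted"):
            DoseResponseLMM().predict(pd.DataFrame())
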