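"""Model forms, OLS fitting with inference, prediction and the PSW line."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.base import clone
from sklearn.exceptions import NotFittedError
from sklearn.pipeline import Pipeline

from shootmass.errors import DomainError, InputError, SingularDesignError
from shootmass.models import (
    BiomassRegressor,
    design_matrix,
    fit_model,
    fit_ols,
    fit_psw_line,
    plant_specific_weight,
    predict,
)

SEED = 20110201


def ols_oracle(X, y):
    """Brute-force normal-equation OLS with classical inference (test oracle)."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n, p = X.shape
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ y
    resid = y - X @ beta
    s2 = resid @ resid / (n - p)
    se = np.sqrt(np.diag(s2 * xtx_inv))
    t = beta / se
    pvals = 2 * stats.t.sf(np.abs(t), n - p)
    tss = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 - resid @ resid / tss
    return beta, se, t, pvals, r2


def obs_frame(area, age=None, sdw=None):
    d = {"area_mm2": np.asarray(area, float)}
    if age is not None:
        d["age_days"] = np.asarray(age, float)
    if sdw is not None:
        d["sdw_g"] = np.asarray(sdw, float)
    return pd.DataFrame(d)


class TestDesignMatrix:
    def test_psw_row_is_intercept_area_interaction(self):
        X, y = design_matrix("psw", obs_frame([100.0], [15.0], [0.5]))
        assert list(X.columns) == ["intercept", "area", "area_age"]
        np.testing.assert_allclose(X.iloc[0], [1.0, 100.0, 1500.0])
        assert y.iloc[0] == 0.5

    def test_cubic_row_is_power_sequence(self):
        X, _ = design_matrix("cubic", obs_frame([2.0], sdw=[1.0]))
        np.testing.assert_allclose(X.iloc[0], [1.0, 2.0, 4.0, 8.0])

    def test_power_form_logs_both_sides(self):
        X, y = design_matrix("power", obs_frame([np.e**2], sdw=[np.e]))
        np.testing.assert_allclose(X.iloc[0], [1.0, 2.0])
        assert y.iloc[0] == pytest.approx(1.0)

    @pytest.mark.parametrize("bad", [{"area": [0.0], "sdw": [1.0]}, {"area": [10.0], "sdw": [0.0]}])
    def test_power_form_rejects_nonpositive_values(self, bad):
        with pytest.raises(DomainError):
            design_matrix("power", obs_frame(bad["area"], sdw=bad["sdw"]))

    def test_unknown_form_and_empty_table(self):
        with pytest.raises(InputError):
            design_matrix("splines", obs_frame([1.0], sdw=[1.0]))
        with pytest.raises(InputError):
            design_matrix("linear", obs_frame([], sdw=[]))


class TestFitOls:
    def test_exact_line_recovers_coefficients_with_zero_residuals(self):
        x = np.arange(1.0, 9.0)
        X = np.column_stack([np.ones_like(x), x])
        fit = fit_ols(X, 2.0 + 3.0 * x)
        np.testing.assert_allclose(fit.params, [2.0, 3.0], atol=1e-12)
        np.testing.assert_allclose(fit.resid, 0.0, atol=1e-12)
        assert fit.rsquared == pytest.approx(1.0)
        assert fit.df_resid == 6

    def test_matches_normal_equation_oracle_on_random_instances(self, rng):
        for _ in range(20):
            n = int(rng.integers(8, 31))
            p = int(rng.integers(2, 5))
            X = np.column_stack([np.ones(n), rng.normal(size=(n, p - 1))])
            y = rng.normal(size=n)
            fit = fit_ols(X, y)
            beta, se, t, pv, r2 = ols_oracle(X, y)
            np.testing.assert_allclose(fit.params, beta, rtol=1e-8)
            np.testing.assert_allclose(fit.bse, se, rtol=1e-8)
            np.testing.assert_allclose(fit.tvalues, t, rtol=1e-8)
            np.testing.assert_allclose(fit.pvalues, pv, rtol=1e-8, atol=1e-12)
            assert fit.rsquared == pytest.approx(r2, rel=1e-8)
            assert fit.df_resid == n - p

    def test_t_is_coefficient_over_standard_error(self, rng):
        X = np.column_stack([np.ones(30), rng.normal(size=(30, 2))])
        fit = fit_ols(X, rng.normal(size=30))
        np.testing.assert_allclose(fit.tvalues, fit.params / fit.bse)

    def test_singular_design_names_offending_column(self):
        x = np.arange(10.0)
        X = pd.DataFrame({"intercept": np.ones(10), "a": x, "a_copy": 2 * x})
        with pytest.raises(SingularDesignError) as err:
            fit_ols(X, x)
        assert set(err.value.columns) & {"a", "a_copy"}

    def test_underdetermined_system_rejected(self):
        with pytest.raises(InputError):
            fit_ols(np.ones((3, 3)), np.ones(3))


class TestFitModel:
    def test_linear_recovers_generating_line(self):
        area = np.linspace(20, 400, 50)
        obs = obs_frame(area, sdw=0.003 * area - 0.043)
        fit = fit_model("linear", obs)
        np.testing.assert_allclose(fit.params, [-0.043, 0.003], atol=1e-12)
        assert fit.units == ("g", "g/mm^2")

    def test_power_recovers_exponent_and_reports_back_transform(self):
        area = np.linspace(10, 400, 60)
        obs = obs_frame(area, sdw=2.0 * area**1.5)
        fit = fit_model("power", obs)
        assert fit.params[1] == pytest.approx(1.5, abs=1e-10)
        assert fit.scale_const == pytest.approx(2.0, rel=1e-10)

    def test_power_fit_is_scale_equivariant(self):
        rng = np.random.default_rng(SEED)
        area = rng.uniform(10, 400, 80)
        sdw = 0.5 * area**1.3 * np.exp(rng.normal(0, 0.1, 80))
        f1 = fit_model("power", obs_frame(area, sdw=sdw))
        f2 = fit_model("power", obs_frame(10.0 * area, sdw=sdw))
        assert f2.params[1] == pytest.approx(f1.params[1], rel=1e-9)
        assert f2.params[0] == pytest.approx(f1.params[0] - f1.params[1] * np.log(10), rel=1e-9)

    def test_quadratic_term_not_significant_on_linear_data(self):
        """Fitting a quadratic to linear-generated data leaves a2 non-significant
        in at least 90% of replicates, mirroring the higher-order-term screen."""
        rng = np.random.default_rng(SEED)
        hits = 0
        for _ in range(200):
            area = rng.uniform(20, 400, 300)
            sdw = -0.043 + 0.003 * area + rng.normal(0, 0.05, 300)
            fit = fit_model("quadratic", obs_frame(area, sdw=sdw))
            hits += fit.pvalues[2] > 0.05
        assert hits >= 180

    def test_interaction_term_never_hurts_in_sample_fit(self, default_dataset):
        obs, _ = default_dataset
        rss_linear = np.sum(fit_model("linear", obs).resid ** 2)
        rss_psw = np.sum(fit_model("psw", obs).resid ** 2)
        assert rss_psw <= rss_linear + 1e-12


class TestPredict:
    def test_age_model_arithmetic_on_reported_coefficients(self, default_dataset):
        obs, _ = default_dataset
        fit = fit_model("psw", obs)
        c = np.array([0.054, -0.001, 9.866e-5])
        got = c[0] + c[1] * 200.0 + c[2] * 200.0 * 26.0
        assert got == pytest.approx(0.367032)
        fake = fit.__class__(**{**fit.__dict__, "params": c})
        assert predict(fake, 200.0, 26.0)[0] == pytest.approx(0.367032)
        assert predict(fake, 0.0, 26.0)[0] == pytest.approx(c[0])

    def test_linear_arithmetic(self):
        area = np.linspace(20, 400, 30)
        fit = fit_model("linear", obs_frame(area, sdw=0.003 * area - 0.043))
        assert predict(fit, 100.0)[0] == pytest.approx(0.257)

    def test_psw_prediction_requires_age(self, noiseless_dataset):
        obs, _ = noiseless_dataset
        fit = fit_model("psw", obs)
        with pytest.raises(InputError):
            predict(fit, 100.0)

    def test_power_prediction_back_transforms(self):
        area = np.linspace(10, 400, 40)
        fit = fit_model("power", obs_frame(area, sdw=2.0 * area**1.5))
        assert predict(fit, 100.0)[0] == pytest.approx(2.0 * 1000.0, rel=1e-8)


class TestPlantSpecificWeight:
    def test_definition_and_degenerate_inputs(self):
        assert plant_specific_weight(0.5, 1000.0) == pytest.approx(5e-4)
        assert plant_specific_weight(0.0, 50.0) == 0.0
        with pytest.raises(DomainError):
            plant_specific_weight(0.5, 0.0)

    def test_noiseless_line_recovered_exactly(self):
        age = np.repeat([15.0, 26.0, 34.0], 5)
        area = np.linspace(30, 300, 15)
        psw = 1e-4 + 2e-5 * age
        obs = obs_frame(area, age, sdw=area * psw)
        line = fit_psw_line(obs)
        assert line.b0 == pytest.approx(1e-4, rel=1e-9)
        assert line.b1 == pytest.approx(2e-5, rel=1e-9)
        assert line(10.0) == pytest.approx(3e-4, rel=1e-9)

    def test_slope_is_positive_on_default_simulation(self, default_dataset):
        obs, truth = default_dataset
        line = fit_psw_line(obs)
        assert line.b1 > 0
        assert line.fit.pvalues[1] < 0.05
        assert line.b1 == pytest.approx(truth["psw_b1"], rel=0.25)

    def test_single_harvest_day_is_degenerate(self):
        obs = obs_frame([10, 20, 30], [26, 26, 26], sdw=[0.1, 0.2, 0.3])
        with pytest.raises(SingularDesignError):
            fit_psw_line(obs)


class TestBiomassRegressor:
    def test_sklearn_protocol_and_parity_with_functions(self, default_dataset):
        obs, _ = default_dataset
        X = obs[["area_mm2", "age_days"]].to_numpy()
        y = obs["sdw_g"].to_numpy()
        est = clone(BiomassRegressor(form="psw")).fit(X, y)
        lib = fit_model("psw", obs)
        np.testing.assert_allclose(est.result_.params, lib.params)
        np.testing.assert_allclose(est.predict(X), predict(lib, X[:, 0], X[:, 1]))
        assert est.intercept_ == lib.params[0]
        assert est.score(X, y) > 0.95  # sklearn RegressorMixin R^2

    def test_works_inside_a_pipeline(self, noiseless_dataset):
        obs, truth = noiseless_dataset
        X = obs[["area_mm2", "age_days"]].to_numpy()
        y = obs["sdw_g"].to_numpy()
        pipe = Pipeline([("model", BiomassRegressor(form="psw"))]).fit(X, y)
        c = truth["model_b_coefficients"]
        np.testing.assert_allclose(
            pipe.named_steps["model"].result_.params,
            [c["c0"], c["c1"], c["c2"]],
            atol=1e-10,
        )

    def test_unfitted_predict_and_missing_age_column(self, default_dataset):
        obs, _ = default_dataset
        with pytest.raises(NotFittedError):
            BiomassRegressor().predict(obs[["area_mm2", "age_days"]].to_numpy())
        with pytest.raises(InputError):
            BiomassRegressor(form="psw").fit(obs[["area_mm2"]].to_numpy(), obs["sdw_g"])
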