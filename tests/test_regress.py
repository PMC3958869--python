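"""OLS machinery, published-model registry and external validation."""

import numpy as np
import pandas as pd
import pytest

from spmekfw.datasets import generate_linear_dataset
from spmekfw.estimators import CollinearityError
from spmekfw.regress import (
    cross_descriptor_r,
    fit_ols,
    forward_selection,
    grouped_mw_correlation,
    pearson_r,
    predict_log_kfw,
    published_model,
    single_parameter_table,
    validate,
)


class TestPearson:
    def test_identity_and_affine(self):
        x = np.array([1.0, 2.0, 5.0, 7.0])
        assert pearson_r(x, x)[0] == pytest.approx(1.0)
        assert pearson_r(x, -2 * x + 7)[0] == pytest.approx(-1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_training_phi_correlation(self, training, log_kfw):
        r, p = pearson_r(training["phi"], log_kfw)
        assert r == pytest.approx(0.977, abs=0.01)
        assert p < 0.05


class TestFitOls:
    def test_exact_recovery_without_noise(self):
        X, y = generate_linear_dataset(rng=0, n=40, beta={"a": 2.5, "b": -1.0}, sigma=0.0, intercept=0.7)
        model = fit_ols(X, y)
        assert model.intercept == pytest.approx(0.7)
        assert model.coefficients["a"] == pytest.approx(2.5)
        assert model.coefficients["b"] == pytest.approx(-1.0)
        assert model.r == pytest.approx(1.0)

    def test_parameter_recovery_within_3_se(self):
        from spmekfw.estimators import KfwRegressor

        beta = {"a": 1.2, "b": -0.4, "c": 0.05}
        X, y = generate_linear_dataset(rng=1234, n=200, beta=beta, sigma=0.5, intercept=2.0)
        reg = KfwRegressor().fit(X, y)
        for j, (name, true) in enumerate(beta.items()):
            assert abs(reg.coef_[j] - true) < 3 * reg.bse_[j + 1], name

    def test_residuals_orthogonal_to_design(self, training, log_kfw):
        from spmekfw.estimators import KfwRegressor

        X = training[["phi", "chi1", "indicator"]]
        reg = KfwRegressor().fit(X, log_kfw)
        resid = log_kfw - reg.predict(X.to_numpy())
        for col in X.columns:
            assert abs(np.dot(resid, training[col])) < 1e-8

    def test_passes_through_centroid(self, training, log_kfw):
        X = training[["phi", "chi1"]]
        model = fit_ols(X, log_kfw)
        assert np.mean(model.predict(training)) == pytest.approx(np.mean(log_kfw))

    def test_collinearity_reported_with_columns(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=30)
        X = pd.DataFrame({"a": a, "b": 2 * a, "c": rng.normal(size=30)})
        with pytest.raises(CollinearityError) as err:
            fit_ols(X, rng.normal(size=30))
        assert {"a", "b"} <= set(err.value.columns)

    def test_refit_matches_published_three_descriptor_model(self, training, log_kfw):
        model = fit_ols(training[["phi", "chi1", "indicator"]], log_kfw)
        assert model.intercept == pytest.approx(1.447, abs=0.02)
        assert model.coefficients["phi"] == pytest.approx(0.728, abs=0.02)
        assert model.coefficients["chi1"] == pytest.approx(0.316, abs=0.02)
        assert model.coefficients["indicator"] == pytest.approx(-0.224, abs=0.02)
        assert model.r == pytest.approx(0.989, abs=0.005)

    def test_refit_single_phi_matches_published(self, training, log_kfw):
        model = fit_ols(training[["phi"]], log_kfw)
        assert model.intercept == pytest.approx(1.933, abs=0.02)
        assert model.coefficients["phi"] == pytest.approx(1.026, abs=0.02)


class TestPublishedModels:
    def test_registry_contents(self):
        eq6 = published_model("eq6")
        assert eq6.intercept == 1.502
        assert eq6.coefficients == {"phi": 0.918, "chi1": 0.177}
        assert published_model("table1_mw").coefficients == {"mw": 0.017}
        assert len(published_model("eq4").coefficients) == 4
        assert published_model("eq4").coefficients["ws"] == 0.001

    def test_unknown_identifier(self):
        with pytest.raises(KeyError):
            published_model("eq7")

    def test_predictions_on_benzene(self):
        d = {"phi": 0.165, "chi1": 2.0, "indicator": 1}
        log5, k5 = predict_log_kfw(published_model("eq5"), d)
        assert log5 == pytest.approx(1.447 + 0.728 * 0.165 + 0.316 * 2 - 0.224)
        assert k5 == pytest.approx(10**log5)
        log6, _ = predict_log_kfw(published_model("eq6"), d)
        assert log6 == pytest.approx(1.502 + 0.918 * 0.165 + 0.177 * 2)

    def test_all_zero_descriptors_give_intercept(self):
        model = published_model("eq5")
        log_kfw, _ = predict_log_kfw(model, {"phi": 0, "chi1": 0, "indicator": 0})
        assert log_kfw == model.intercept

    def test_missing_descriptor_named(self):
        with pytest.raises(KeyError, match="ws"):
            predict_log_kfw(published_model("eq4"), {"phi": 0, "chi1": 0, "indicator": 0})


class TestSingleParameterTable:
    def test_matches_published_rows(self, training):
        table = single_parameter_table(training)
        # (intercept, slope, |r|) as published; MW row is the loose one
        expected = {
            "phi": (1.933, 1.026, 0.977, 0.01),
            "log_kow": (0.319, 0.881, 0.774, 0.01),
            "chi1": (0.750, 0.862, 0.743, 0.01),
            "indicator": (4.144, -0.846, 0.583, 0.01),
            "ws": (3.936, -0.002, 0.559, 0.01),
            "mw": (1.859, 0.017, 0.474, 0.06),
        }
        for col, (b0, b1, r, rtol) in expected.items():
            m = table[col]
            assert m.intercept == pytest.approx(b0, abs=0.06), col
            assert m.coefficients[col] == pytest.approx(b1, abs=0.02), col
            assert abs(m.r) == pytest.approx(r, abs=rtol), col

    def test_slope_times_sd_ratio_equals_r(self, training, log_kfw):
        table = single_parameter_table(training)
        for col, m in table.items():
            sd_ratio = np.std(training[col], ddof=1) / np.std(log_kfw, ddof=1)
            assert m.coefficients[col] * sd_ratio == pytest.approx(m.r, abs=1e-9), col


class TestCrossDescriptor:
    def test_chi_phi_published(self, training):
        assert cross_descriptor_r(training, "chi1", "phi") == pytest.approx(0.676, abs=0.01)

    def test_self_correlation(self, training):
        assert cross_descriptor_r(training, "phi", "phi") == 1.0

    def test_collinear_columns(self):
        df = pd.DataFrame({"chi1": [1.0, 2.0, 3.0], "mw": [10.0, 20.0, 30.0]})
        assert cross_descriptor_r(df, "chi1", "mw") == pytest.approx(1.0)


class TestGroupedMw:
    def test_default_structural_grouping(self, training):
        rs = grouped_mw_correlation(training)
        assert set(rs) == {"alkane", "aromatic"}
        assert rs["alkane"] >= 0.916
        assert rs["aromatic"] >= 0.916

    def test_pooled_correlation_is_much_weaker(self, training, log_kfw):
        pooled, _ = pearson_r(training["mw"], log_kfw)
        assert pooled == pytest.approx(0.474, abs=0.06)
        assert pooled < 0.6

    def test_perfectly_collinear_group(self):
        df = pd.DataFrame(
            {
                "name": list("abcdef"),
                "smiles": ["C"] * 6,
                "kfw": 10.0 ** np.array([1, 2, 3, 1.5, 2.5, 3.5]),
                "mw": [10, 20, 30, 15, 25, 35],
            }
        )
        groups = pd.Series(["g1"] * 3 + ["g2"] * 3, index=df.index)
        rs = grouped_mw_correlation(df, groups)
        assert rs["g1"] == pytest.approx(1.0)
        assert rs["g2"] == pytest.approx(1.0)

    def test_small_group_rejected(self, training):
        groups = pd.Series(["a"] * 2 + ["b"] * (len(training) - 2), index=training.index)
        with pytest.raises(ValueError, match="fewer than 3"):
            grouped_mw_correlation(training, groups)


class TestValidate:
    def test_self_prediction_is_perfect(self):
        X, y = generate_linear_dataset(rng=7, n=30, beta={"phi": 1.0, "chi1": 0.5}, sigma=0.0, intercept=1.0)
        model = fit_ols(X, y)
        df = X.copy()
        df["kfw"] = 10.0**y
        df["name"] = [f"s{i}" for i in range(len(df))]
        report = validate(model, df, scale="log")
        assert report.r_obs_pred == pytest.approx(1.0)
        assert report.slope == pytest.approx(1.0)
        assert report.intercept == pytest.approx(0.0, abs=1e-9)

    def test_published_three_descriptor_model_on_test_set(self, test_set):
        report = validate(published_model("eq5"), test_set, scale="log")
        assert report.n == 26
        # the proportional (through-origin) log-scale R reproduces the
        # published external-validation figure
        assert report.proportional_r == pytest.approx(0.819, abs=0.01)
        # plain Pearson r on either scale is far lower — documented behaviour
        assert report.r_obs_pred == pytest.approx(0.544, abs=0.01)

    def test_two_descriptor_model_on_test_set(self, test_set):
        report = validate(published_model("eq6"), test_set, scale="log")
        assert report.proportional_r > 0.77

    def test_residuals_table_complete(self, test_set):
        report = validate(published_model("eq5"), test_set)
        assert len(report.residuals) == 26
        assert {"observed_log_kfw", "predicted_log_kfw", "residual"} <= set(report.residuals.columns)


class TestForwardSelection:
    def test_selects_strong_predictors_on_synthetic(self):
        rng = np.random.default_rng(5)
        n = 120
        df = pd.DataFrame(
            {
                "phi": rng.normal(size=n),
                "chi1": rng.normal(size=n),
                "indicator": rng.integers(0, 2, size=n).astype(float),
                "ws": rng.normal(size=n),
            }
        )
        log_k = 1.0 + 0.9 * df["phi"] + 0.5 * df["chi1"] + rng.normal(scale=0.1, size=n)
        df["kfw"] = 10.0**log_k
        model = forward_selection(df)
        assert {"phi", "chi1"} <= set(model.coefficients)
        assert "ws" not in model.coefficients

    def test_training_set_keeps_phi_first(self, training):
        model = forward_selection(training)
        assert "phi" in model.coefficients
        assert model.r >= 0.98
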