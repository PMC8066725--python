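"""Quadratic surface fitting, ANOVA and prediction."""

import numpy as np
import pytest

from chromdoe.doe import generate_bbd
from chromdoe.errors import ValidationError
from chromdoe.rsm import (
    COEF_NAMES,
    QuadraticModel,
    anova_effects,
    fit_quadratic,
    model_matrix,
    predict,
    r_squared,
    surface_slice,
)

# run-time model printed in the study, in COEF_NAMES order
RT_COEFS = {
    "b0": 2.765,
    "b1": -0.183125,
    "b2": -0.29425,
    "b3": -0.442875,
    "b11": 0.043,
    "b22": -0.02375,
    "b33": 0.1315,
    "b12": -0.01425,
    "b13": 0.0105,
    "b23": 0.08175,
}


class TestFitQuadratic:
    def test_reproduces_printed_run_time_coefficients(self, run_time_model):
        fitted = run_time_model.named_coefficients()
        for name, expected in RT_COEFS.items():
            assert fitted[name] == pytest.approx(expected, abs=1e-9), name

    def test_closed_forms_on_orthogonal_design(self, study_table):
        # intercept = mean of center runs; linear = (sum at +1 - sum at -1)/8;
        # interaction = sum(xi*xj*y)/4  -- all exact for the BBD
        design, responses = study_table
        y = responses["run_time"]
        X = design.runs
        centers = (X == 0).all(axis=1)
        model = fit_quadratic(design, y)
        assert model.beta0 == pytest.approx(y[centers].mean(), abs=1e-9)
        for j in range(3):
            lin = (y[X[:, j] == 1].sum() - y[X[:, j] == -1].sum()) / 8
            assert model.linear[j] == pytest.approx(lin, abs=1e-9)
        for m, (i, j) in enumerate([(0, 1), (0, 2), (1, 2)]):
            inter = (X[:, i] * X[:, j] * y).sum() / 4
            assert model.interactions[m] == pytest.approx(inter, abs=1e-9)

    def test_constant_response_convention(self, study_table):
        design, _ = study_table
        with pytest.warns(UserWarning, match="degenerate"):
            model = fit_quadratic(design, np.full(15, 4.2))
        assert model.beta0 == pytest.approx(4.2)
        np.testing.assert_allclose(model.coefficients[1:], 0, atol=1e-12)
        assert model.r_squared == 0.0

    def test_noiseless_recovery(self, study_table, rng):
        design, _ = study_table
        truth = rng.normal(size=10)
        y = model_matrix(design.runs) @ truth
        model = fit_quadratic(design, y)
        np.testing.assert_allclose(model.coefficients, truth, atol=1e-9)

    def test_residuals_orthogonal_to_model_columns(self, study_table, all_models):
        design, responses = study_table
        M = model_matrix(design.runs)
        for name, model in all_models.items():
            resid = responses[name] - M @ model.coefficients
            assert np.abs(M.T @ resid).max() < 1e-8

    def test_length_mismatch_rejected(self, study_table):
        design, _ = study_table
        with pytest.raises(ValidationError):
            fit_quadratic(design, np.ones(14))

    def test_too_few_runs_rejected(self, factors):
        design = generate_bbd(factors, n_center=3)
        from chromdoe.doe import DesignTable

        small = DesignTable(factors=design.factors, runs=design.runs[:10])
        with pytest.raises(ValidationError):
            fit_quadratic(small, np.ones(10))


class TestPredict:
    def test_origin_returns_intercept(self, run_time_model):
        assert predict(run_time_model, (0, 0, 0)) == pytest.approx(
            run_time_model.beta0
        )

    def test_hand_sum_at_unit_flow(self):
        # printed model evaluated at (1, 0, 0): b0 + b1 + b11
        model = QuadraticModel(
            response_name="run_time",
            coefficients=np.array([RT_COEFS[n] for n in COEF_NAMES]),
        )
        assert predict(model, (1.0, 0.0, 0.0)) == pytest.approx(2.624875, abs=1e-12)

    def test_zero_model_predicts_zero(self):
        model = QuadraticModel(response_name="zero", coefficients=np.zeros(10))
        assert predict(model, (0.3, -0.7, 0.9)) == 0.0

    def test_extrapolation_warns(self, run_time_model):
        import chromdoe.rsm as rsm

        with pytest.warns(rsm.ExtrapolationWarning):
            predict(run_time_model, (2.0, 0.0, 0.0))


class TestRSquared:
    def test_run_time_r2_matches_report(self, study_table, run_time_model):
        design, responses = study_table
        assert r_squared(run_time_model, design, responses["run_time"]) == pytest.approx(
            0.9994, abs=5e-5
        )

    def test_saturated_fit_is_exact(self, factors, rng):
        from chromdoe.doe import DesignTable

        # 10 edge runs + 1 center: rank-10 design, noiseless data
        design = generate_bbd(factors, n_center=1)
        rows = np.vstack([design.runs[:10], design.runs[12]])
        sub = DesignTable(factors=design.factors, runs=rows)
        y = model_matrix(sub.runs) @ rng.normal(size=10)
        model = fit_quadratic(sub, y)
        assert r_squared(model, sub, y) == pytest.approx(1.0, abs=1e-9)

    def test_matches_independent_ols_oracle(self, study_table, rng):
        import statsmodels.api as sm

        design, _ = study_table
        M = model_matrix(design.runs)
        for _ in range(5):
            y = rng.normal(size=15)
            model = fit_quadratic(design, y)
            oracle = sm.OLS(y, M).fit()
            assert model.r_squared == pytest.approx(oracle.rsquared, abs=1e-10)


class TestAnova:
    def test_all_linear_run_time_effects_significant(
        self, study_table, run_time_model
    ):
        design, responses = study_table
        table = anova_effects(run_time_model, design, responses["run_time"])
        assert (table.effects.loc[["x1", "x2", "x3"], "p"] < 0.05).all()

    def test_f_equals_squared_t_from_ols_oracle(self, study_table, rng):
        import statsmodels.api as sm

        design, _ = study_table
        M = model_matrix(design.runs)
        y = rng.normal(size=15) + M[:, 1]
        model = fit_quadratic(design, y)
        table = anova_effects(model, design, y)
        oracle = sm.OLS(y, M).fit()
        np.testing.assert_allclose(
            table.effects["f"].to_numpy(), oracle.tvalues[1:] ** 2, rtol=1e-9
        )
        np.testing.assert_allclose(
            table.effects["p"].to_numpy(), oracle.pvalues[1:], rtol=1e-9
        )

    def test_type_i_error_rate_near_alpha(self, study_table):
        # response independent of x1: its linear effect should be rejected
        # at 5% in roughly 5% of replicates
        design, _ = study_table
        rng = np.random.default_rng(5)
        rejections = 0
        n_rep = 200
        for _ in range(n_rep):
            y = 1.0 + rng.normal(0, 0.01, size=15)
            model = fit_quadratic(design, y)
            table = anova_effects(model, design, y)
            rejections += table.effects.loc["x1", "p"] < 0.05
        assert rejections / n_rep == pytest.approx(0.05, abs=0.02 + 2 / n_rep)

    def test_sequential_decomposition_is_exact(self, study_table):
        # projecting out terms one at a time decomposes SST exactly; the
        # linear and interaction partial SS coincide with their sequential
        # values because those columns are orthogonal to all others
        design, responses = study_table
        y = responses["run_time"]
        M = model_matrix(design.runs)
        sst = np.sum((y - y.mean()) ** 2)
        seq_ss = []
        for j in range(1, 10):
            sub = M[:, : j + 1]
            prev = M[:, :j]
            sse_prev = np.sum((y - prev @ np.linalg.lstsq(prev, y, rcond=None)[0]) ** 2)
            sse_cur = np.sum((y - sub @ np.linalg.lstsq(sub, y, rcond=None)[0]) ** 2)
            seq_ss.append(sse_prev - sse_cur)
        model = fit_quadratic(design, y)
        table = anova_effects(model, design, y)
        resid_ss = table.residual_ss
        assert sum(seq_ss) + resid_ss == pytest.approx(sst, rel=1e-10)
        partial = table.effects["ss"].to_numpy()
        for idx in (0, 1, 2, 6, 7, 8):  # linear + interaction slots
            assert partial[idx] == pytest.approx(seq_ss[idx], rel=1e-9)
        # quadratic columns are only near-orthogonal: partial SS sum is
        # close to, but not exactly, the sequential decomposition
        assert sum(partial) + resid_ss == pytest.approx(sst, rel=1e-4)

    def test_signs_follow_coefficients(self, study_table, run_time_model):
        design, responses = study_table
        table = anova_effects(run_time_model, design, responses["run_time"])
        np.testing.assert_array_equal(
            table.effects["sign"].to_numpy(),
            np.sign(run_time_model.coefficients[1:]).astype(int),
        )


class TestNoiseProperties:
    def test_linear_coefficient_standard_error(self, study_table):
        # var(b_linear) = sigma^2 / sum(x^2) = sigma^2 / 8 on the BBD
        design, _ = study_table
        rng = np.random.default_rng(11)
        sigma = 0.1
        M = model_matrix(design.runs)
        H = np.linalg.inv(M.T @ M) @ M.T
        noise = rng.normal(0, sigma, size=(600, 15))
        coefs = noise @ H.T  # (600, 10); truth is the zero vector
        empirical_se = coefs[:, 1:4].std(axis=0, ddof=1)
        np.testing.assert_allclose(empirical_se, sigma / np.sqrt(8), rtol=0.10)


class TestSurfaceSlice:
    def test_corners_match_pointwise_prediction(self, run_time_model):
        gx, gy, z = surface_slice(run_time_model, ("pctB_start", "pctB_end"), 0.0, 2)
        for i, xi in enumerate(gx):
            for j, yj in enumerate(gy):
                assert z[i, j] == pytest.approx(
                    predict(run_time_model, (0.0, xi, yj)), abs=1e-12
                )

    def test_dense_grid_matches_pointwise(self, run_time_model):
        gx, gy, z = surface_slice(run_time_model, (1, 2), {"flow": 0.0}, 21)
        i, j = 7, 13
        assert z[i, j] == pytest.approx(
            predict(run_time_model, (0.0, gx[i], gy[j])), abs=1e-12
        )

    def test_zero_model_gives_zero_grid(self):
        model = QuadraticModel(response_name="zero", coefficients=np.zeros(10))
        _, _, z = surface_slice(model, (0, 1), 0.0, 5)
        assert (z == 0).all()

    def test_unknown_factor_rejected(self, run_time_model):
        with pytest.raises(ValidationError):
            surface_slice(run_time_model, ("flow", "nope"), 0.0, 5)


class TestModelJson:
    def test_round_trip(self, run_time_model):
        clone = QuadraticModel.from_json(run_time_model.to_json())
        np.testing.assert_allclose(clone.coefficients, run_time_model.coefficients)
        assert clone.response_name == run_time_model.response_name
        assert clone.r_squared == pytest.approx(run_time_model.r_squared)
        assert [f.name for f in clone.factors] == [
            f.name for f in run_time_model.factors
        ]
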