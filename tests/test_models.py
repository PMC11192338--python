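"""Baseline regressors and the natively implemented networks."""

import numpy as np
import pytest

from cgmi.evaluation import r2_eq_ratio
from cgmi.models import (
    MODEL_NAMES,
    ModelConfig,
    bpnn_forward,
    bpnn_param_count,
    fit_model,
    predict,
    train_bpnn,
)


def test_param_count_for_default_architecture():
    # 5 inputs, 12 hidden tanh units, 1 linear output
    assert bpnn_param_count(5, 12) == 85


def test_config_rejects_unknown_keys_and_nonpositive_values():
    with pytest.raises(ValueError, match="unknown hyperparameters"):
        ModelConfig("BPNN", {"neurons": 9})
    with pytest.raises(ValueError, match="positive"):
        ModelConfig("SVR", {"penalty": -1})
    with pytest.raises(ValueError, match="unknown model"):
        ModelConfig("XGB")


class TestBPNNForward:
    def test_zero_params_give_zero_output(self):
        X = np.random.default_rng(0).normal(size=(10, 5))
        np.testing.assert_allclose(bpnn_forward(np.zeros(85), X), 0.0)

    def test_only_output_bias_gives_constant(self):
        params = np.zeros(85)
        params[-1] = 3.25
        X = np.random.default_rng(0).normal(size=(7, 5))
        np.testing.assert_allclose(bpnn_forward(params, X), 3.25)

    def test_scalar_toy_network(self):
        # 1 input, 1 hidden unit: w1=1, b1=0, w2=2, b2=0.5 at x=0.5
        params = np.array([1.0, 0.0, 2.0, 0.5])
        out = bpnn_forward(params, [[0.5]], hidden=1)
        assert out[0] == pytest.approx(2 * np.tanh(0.5) + 0.5, abs=1e-12)

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError, match="parameters"):
            bpnn_forward(np.zeros(10), np.zeros((2, 5)))


class TestBPNNTraining:
    def test_reaches_goal_on_noise_free_linear_data(self):
        rng = np.random.default_rng(5)
        X = rng.uniform(0, 1, size=(200, 5))
        y = X @ np.array([1.0, -0.5, 0.25, 0.8, -0.2]) + 0.3
        cfg = ModelConfig("BPNN", {"val_fraction": 0.0}, seed=0)
        model = train_bpnn(X, y, cfg)
        assert model.final_loss <= 1e-4

    def test_warm_start_with_zero_iterations_is_identity(self, linear_regression_data):
        X, y = linear_regression_data
        trained = train_bpnn(X, y, ModelConfig("BPNN", seed=1))
        again = train_bpnn(
            X, y, ModelConfig("BPNN", {"max_iter": 0}, seed=1),
            init=trained.state["params"],
        )
        np.testing.assert_array_equal(
            predict(trained, X), predict(again, X)
        )

    def test_same_seed_identical_loss_traces(self, linear_regression_data):
        X, y = linear_regression_data
        a = train_bpnn(X, y, ModelConfig("BPNN", seed=3))
        b = train_bpnn(X, y, ModelConfig("BPNN", seed=3))
        np.testing.assert_array_equal(a.loss_trace, b.loss_trace)

    def test_gradient_descent_fallback_honours_batches(self, linear_regression_data):
        X, y = linear_regression_data
        cfg = ModelConfig("BPNN", {"algorithm": "gd", "max_iter": 50}, seed=0)
        model = train_bpnn(X, y, cfg)
        assert model.loss_trace[-1] < model.loss_trace[0]

    def test_non_finite_input_rejected(self):
        X = np.full((10, 2), np.nan)
        with pytest.raises(ValueError, match="non-finite"):
            train_bpnn(X, np.zeros(10))


class TestBaselines:
    def test_mlr_recovers_exact_coefficients(self, linear_regression_data):
        X, y = linear_regression_data
        model = fit_model("MLR", X, y)
        np.testing.assert_allclose(model.state.coef_, [3.0, -2.0], atol=1e-8)
        assert model.state.intercept_ == pytest.approx(1.0, abs=1e-8)

    def test_mlr_singular_design_names_collinear_column(self):
        rng = np.random.default_rng(0)
        x0 = rng.normal(size=30)
        X = np.column_stack([x0, 2 * x0, rng.normal(size=30)])
        with pytest.raises(ValueError, match="collinear"):
            fit_model("MLR", X, x0)

    def test_full_rank_pls_matches_ols(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(30, 3))
        y = X @ [1.0, 2.0, -1.0] + 0.5 + 0.01 * rng.normal(size=30)
        mlr = fit_model("MLR", X, y)
        pls = fit_model("PLS", X, y, ModelConfig("PLS", {"n_components": 3}))
        X_new = rng.normal(size=(10, 3))
        np.testing.assert_allclose(predict(pls, X_new), predict(mlr, X_new), atol=1e-6)

    def test_rf_recovers_step_plateau(self):
        X = np.linspace(0, 1, 20).reshape(-1, 1)
        y = (X[:, 0] >= 0.5).astype(float)
        model = fit_model("RF", X, y, ModelConfig("RF", seed=0))
        assert predict(model, [[0.05]])[0] == pytest.approx(0.0, abs=0.1)
        assert predict(model, [[0.95]])[0] == pytest.approx(1.0, abs=0.1)

    def test_rbfnn_improves_on_mean_predictor(self):
        rng = np.random.default_rng(2)
        X = rng.uniform(0, 1, size=(40, 2))
        y = np.sin(3 * X[:, 0]) + X[:, 1] ** 2
        model = fit_model("RBFNN", X, y)
        assert model.final_loss < np.var(y)

    @pytest.mark.parametrize("name", MODEL_NAMES)
    def test_fit_predict_deterministic_and_r2_nonneg(self, name, linear_regression_data):
        X, y = linear_regression_data
        m1 = fit_model(name, X, y, ModelConfig(name, seed=0))
        m2 = fit_model(name, X, y, ModelConfig(name, seed=0))
        p1, p2 = predict(m1, X), predict(m2, X)
        np.testing.assert_array_equal(p1, p2)
        assert r2_eq_ratio(p1, y) >= 0.0

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError, match="5 training rows"):
            fit_model("MLR", np.zeros((3, 2)), np.zeros(3))
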