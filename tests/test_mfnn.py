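"""Surrogate models: standardization, loss contract, architecture invariants."""

import numpy as np
import pytest

from pulmoflow.mfnn import (
    MultiFidelityRegression,
    SingleFidelityRegression,
    Standardizer,
    SubnetHyperparams,
    TrainingConfig,
    TrainingError,
    mse,
    standardize,
)

SMALL_LOW = SubnetHyperparams(1e-4, 16, 2, "tanh")


def linear_link_data(seed=0, NL=200, NH=20, noise=0.0):
    """LF scores from a smooth map of x; HF scores an exact affine link."""
    rng = np.random.default_rng(seed)
    XL = rng.uniform(-1, 1, (NL, 7))
    XH = rng.uniform(-1, 1, (NH, 7))
    Xt = rng.uniform(-1, 1, (30, 7))

    def g(X):
        return np.stack(
            [
                2.0 + np.tanh(X[:, 0]) + 0.5 * X[:, 1] * X[:, 2],
                -1.0 + np.sin(X[:, 3]) + 0.3 * X[:, 4],
            ],
            axis=1,
        )

    A = np.array([[1.2, -0.3], [0.1, 0.8], [0.4, 0.4]])
    b = np.array([0.5, -0.2, 0.1])

    def f_high(X):
        return g(X) @ A.T + b

    YL = g(XL) + noise * rng.normal(size=(NL, 2))
    YH = f_high(XH) + noise * rng.normal(size=(NH, 3))
    return XL, YL, XH, YH, Xt, f_high, g, A, b


class TestStandardize:
    def test_two_point_column(self):
        Xs, stats = standardize(np.array([[3.0], [9.0]]))
        np.testing.assert_allclose(Xs.ravel(), [-1.0, 1.0])  # population sd
        assert stats.mean[0] == 6.0 and stats.sd[0] == 3.0

    def test_apply_mode_reuses_training_stats(self):
        rng = np.random.default_rng(0)
        X = rng.normal(2.0, 3.0, size=(50, 4))
        Xs, stats = standardize(X)
        assert np.max(np.abs(Xs.mean(axis=0))) < 1e-12
        np.testing.assert_allclose(Xs.std(axis=0), 1.0, rtol=1e-12)
        X2, _ = standardize(X[:10], stats)
        np.testing.assert_allclose(X2, (X[:10] - stats.mean) / stats.sd)
        np.testing.assert_allclose(stats.inverse(Xs), X)

    def test_constant_column_error_names_column(self):
        X = np.column_stack([np.arange(5.0), np.full(5, 2.0)])
        with pytest.raises(ValueError, match="1"):
            Standardizer.fit(X)


class TestLossContract:
    def test_mse_example_and_shape_check(self):
        assert mse(np.array([1.0, 2.0]), np.array([0.0, 0.0])) == pytest.approx(2.5)
        with pytest.raises(ValueError):
            mse(np.zeros(3), np.zeros(4))

    def test_zero_model_zero_targets_zero_lambda(self):
        rng = np.random.default_rng(1)
        XL, XH = rng.normal(size=(20, 7)), rng.normal(size=(5, 7))
        model = MultiFidelityRegression(
            XL,
            np.zeros((20, 2)),
            XH,
            np.zeros((5, 2)),
            reg_lambda=0.0,
            n_neurons=8,
            n_layers=2,
            low_hyperparams=SubnetHyperparams(0.0, 8, 2, "tanh"),
            scale_targets=False,
        )
        assert model.loss(np.zeros(model.n_params)) == 0.0

    def test_loss_additivity_in_regularization(self):
        rng = np.random.default_rng(2)
        XL, XH = rng.normal(size=(20, 7)), rng.normal(size=(6, 7))
        YL, YH = rng.normal(size=(20, 2)), rng.normal(size=(6, 3))
        kwargs = dict(n_neurons=8, n_layers=2, scale_targets=False)
        m0 = MultiFidelityRegression(
            XL, YL, XH, YH, reg_lambda=0.0,
            low_hyperparams=SubnetHyperparams(0.0, 8, 2, "tanh"), **kwargs
        )
        lam = 0.37
        m1 = MultiFidelityRegression(
            XL, YL, XH, YH, reg_lambda=lam,
            low_hyperparams=SubnetHyperparams(0.05, 8, 2, "tanh"), **kwargs
        )
        for seed in (0, 1, 2):
            theta = m1.initialize(seed)
            expected = m1.penalty(theta)
            assert m1.loss(theta) - m0.loss(theta) == pytest.approx(expected, rel=1e-12)


class TestArchitectureInvariants:
    @pytest.fixture(scope="class")
    def fitted(self):
        XL, YL, XH, YH, *_ = linear_link_data(seed=3, NL=60, NH=10)
        model = MultiFidelityRegression(
            XL, YL, XH, YH, n_neurons=12, n_layers=2,
            low_hyperparams=SMALL_LOW,
        )
        return model.fit(TrainingConfig(epochs=120, seed=0))

    def test_linear_subnet_is_affine(self, fitted):
        # second differences of NN_H1 vanish: no activation anywhere
        model = fitted.model
        params = model.net_lin.views(fitted.params[model._slices[1]])
        rng = np.random.default_rng(4)
        d = model.X_high.shape[1] + model.k_low
        v1, v2 = rng.normal(size=(2, 1, d))
        f = lambda v: model.net_lin.forward(params, v)[0]
        second_diff = f(v1 + v2) - f(v1) - f(v2) + f(np.zeros((1, d)))
        assert np.max(np.abs(second_diff)) < 1e-10

    def test_nonlinear_subnet_is_not_affine(self, fitted):
        model = fitted.model
        params = model.net_nl.views(fitted.params[model._slices[2]])
        rng = np.random.default_rng(5)
        d = model.X_high.shape[1] + model.k_low
        v1, v2 = rng.normal(size=(2, 1, d))
        f = lambda v: model.net_nl.forward(params, v)[0]
        second_diff = f(v1 + v2) - f(v1) - f(v2) + f(np.zeros((1, d)))
        assert np.max(np.abs(second_diff)) > 1e-8

    def test_prediction_is_sum_of_subnet_outputs(self, fitted):
        rng = np.random.default_rng(6)
        X = rng.uniform(-1, 1, (8, 7))
        o1, o2 = fitted.predict_components(X)
        expected = fitted.model.scaler_high.inverse(o1 + o2)
        np.testing.assert_allclose(fitted.predict(X), expected, rtol=1e-12)

    def test_unscaled_prediction_is_literal_sum(self):
        XL, YL, XH, YH, *_ = linear_link_data(seed=7, NL=40, NH=8)
        res = MultiFidelityRegression(
            XL, YL, XH, YH, n_neurons=8, n_layers=1,
            low_hyperparams=SMALL_LOW, scale_targets=False,
        ).fit(TrainingConfig(epochs=50, seed=0))
        X = XH[:3]
        o1, o2 = res.predict_components(X)
        np.testing.assert_allclose(res.predict(X), o1 + o2, rtol=1e-12)

    def test_batch_equals_per_sample(self, fitted):
        rng = np.random.default_rng(8)
        X = rng.uniform(-1, 1, (5, 7))
        batch = fitted.predict(X)
        singles = np.vstack([fitted.predict(X[i]) for i in range(5)])
        np.testing.assert_allclose(batch, singles, rtol=1e-12)

    def test_wrong_input_width(self, fitted):
        with pytest.raises(ValueError):
            fitted.predict(np.zeros((2, 5)))

    def test_loss_decreases_and_seed_determinism(self):
        XL, YL, XH, YH, *_ = linear_link_data(seed=9, NL=50, NH=8)
        make = lambda: MultiFidelityRegression(
            XL, YL, XH, YH, n_neurons=10, n_layers=2, low_hyperparams=SMALL_LOW
        )
        cfg = TrainingConfig(epochs=100, seed=11)
        r1, r2 = make().fit(cfg), make().fit(cfg)
        assert r1.final_loss < r1.loss_trace[0]
        np.testing.assert_array_equal(r1.params, r2.params)
        r3 = make().fit(TrainingConfig(epochs=100, seed=12))
        assert not np.array_equal(r1.params, r3.params)


class TestRecoveryBenchmarks:
    def test_linear_fidelity_link_recovered(self):
        # HF scores are an exact affine function of LF scores: the composite
        # should generalize nearly perfectly from 20 HF samples
        XL, YL, XH, YH, Xt, f_high, *_ = linear_link_data(seed=10, NL=200, NH=20)
        res = MultiFidelityRegression(
            XL, YL, XH, YH, reg_lambda=1e-5, n_neurons=20, n_layers=2,
            low_hyperparams=SubnetHyperparams(1e-5, 30, 3, "tanh"),
        ).fit(TrainingConfig(epochs=3000, seed=1))
        from pulmoflow.evaluation import r2_score

        assert r2_score(f_high(Xt), res.predict(Xt)) >= 0.99

    def test_linear_map_coefficients_recovered(self):
        # identifiable form of the linear-correlation claim: the end-to-end
        # map x -> yH is A.g(x) + b; compare the fitted composite against it
        # on probe points via least squares onto the true LF features
        XL, YL, XH, YH, Xt, f_high, g, A, b = linear_link_data(seed=12, NL=300, NH=20)
        res = MultiFidelityRegression(
            XL, YL, XH, YH, reg_lambda=1e-6, n_neurons=20, n_layers=2,
            low_hyperparams=SubnetHyperparams(1e-6, 40, 3, "tanh"),
        ).fit(TrainingConfig(epochs=5000, seed=2))
        pred = res.predict(Xt)
        design = np.column_stack([g(Xt), np.ones(len(Xt))])
        coef, *_ = np.linalg.lstsq(design, pred, rcond=None)
        affine_fit = np.column_stack([coef[:-1].T, coef[-1]])
        affine_true = np.column_stack([A, b])
        rel = np.linalg.norm(affine_fit - affine_true) / np.linalg.norm(affine_true)
        assert rel < 0.10

    def test_single_fidelity_capacity_on_smooth_map(self):
        rng = np.random.default_rng(13)
        X = rng.uniform(-1, 1, (200, 1))
        y = np.sin(2.5 * X) + 0.3 * X**2
        Xt = rng.uniform(-1, 1, (50, 1))
        res = SingleFidelityRegression(
            X, y, reg_lambda=1e-6, n_neurons=20, n_layers=2
        ).fit(TrainingConfig(epochs=2000, seed=3))
        from pulmoflow.evaluation import r2_score

        assert r2_score(np.sin(2.5 * Xt) + 0.3 * Xt**2, res.predict(Xt)) >= 0.99

    def test_single_fidelity_determinism_and_shape(self):
        rng = np.random.default_rng(14)
        X, y = rng.normal(size=(20, 7)), rng.normal(size=(20, 2))
        cfg = TrainingConfig(epochs=60, seed=5)
        r1 = SingleFidelityRegression(X, y, n_neurons=8, n_layers=2).fit(cfg)
        r2 = SingleFidelityRegression(X, y, n_neurons=8, n_layers=2).fit(cfg)
        np.testing.assert_array_equal(r1.params, r2.params)
        assert r1.predict(X[:4]).shape == (4, 2)


class TestValidationAndFailure:
    def test_regime_and_shape_checks(self):
        rng = np.random.default_rng(15)
        with pytest.raises(ValueError):  # N_L < N_H
            MultiFidelityRegression(
                rng.normal(size=(5, 7)), rng.normal(size=(5, 2)),
                rng.normal(size=(10, 7)), rng.normal(size=(10, 2)),
            )
        with pytest.raises(ValueError):  # row mismatch
            MultiFidelityRegression(
                rng.normal(size=(20, 7)), rng.normal(size=(19, 2)),
                rng.normal(size=(5, 7)), rng.normal(size=(5, 2)),
            )

    @pytest.mark.filterwarnings("ignore::RuntimeWarning")
    def test_divergent_training_raises(self):
        rng = np.random.default_rng(16)
        X, y = rng.normal(size=(10, 3)), 1e3 * rng.normal(size=(10, 2))
        model = SingleFidelityRegression(
            X, y, reg_lambda=1.0, n_neurons=8, n_layers=2,
            activation="relu", scale_targets=False,
        )
        with pytest.raises(TrainingError):
            model.fit(TrainingConfig(learning_rate=1e200, epochs=50, seed=0))

    def test_pretraining_flag_runs(self):
        XL, YL, XH, YH, *_ = linear_link_data(seed=17, NL=40, NH=8)
        res = MultiFidelityRegression(
            XL, YL, XH, YH, n_neurons=8, n_layers=1, low_hyperparams=SMALL_LOW
        ).fit(TrainingConfig(epochs=40, seed=0, pretrain_low_epochs=30))
        assert res.loss_trace.size == 70

    def test_summary_mentions_architecture(self):
        XL, YL, XH, YH, *_ = linear_link_data(seed=18, NL=40, NH=8)
        res = MultiFidelityRegression(
            XL, YL, XH, YH, n_neurons=8, n_layers=1, low_hyperparams=SMALL_LOW
        ).fit(TrainingConfig(epochs=5, seed=0))
        text = res.summary()
        assert "rMFNN" in text and "NN_H1" in text and "affine" in text
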