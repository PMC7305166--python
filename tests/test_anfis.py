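"""FCM clustering and the Takagi–Sugeno neuro-fuzzy regressor."""

import numpy as np
import pytest

from ipfpvol.anfis import (
    FISModel,
    TrainConfig,
    evaluate_fis,
    fcm_cluster,
    fit_anfis,
    init_fis_from_fcm,
    train_hybrid,
)


def _ols_predictions(X, y, Xq):
    A = np.column_stack([X, np.ones(len(X))])
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    return np.column_stack([Xq, np.ones(len(Xq))]) @ beta


class TestFCM:
    def test_single_cluster_closed_form(self, rng):
        X = rng.normal(size=(50, 3))
        res = fcm_cluster(X, c=1, seed=0)
        np.testing.assert_allclose(res.centers[0], X.mean(axis=0), atol=1e-9)
        np.testing.assert_allclose(res.memberships, 1.0)

    def test_two_separated_blobs(self):
        rng = np.random.default_rng(0)
        a = rng.normal(-10, 0.5, size=(200, 2))
        b = rng.normal(10, 0.5, size=(200, 2))
        X = np.vstack([a, b])
        res = fcm_cluster(X, c=2, seed=4)
        means = np.array([a.mean(axis=0), b.mean(axis=0)])
        # match centers to blobs by sign of the first coordinate
        order = np.argsort(res.centers[:, 0])
        np.testing.assert_allclose(res.centers[order], means[np.argsort(means[:, 0])], atol=0.2)

    @pytest.mark.parametrize("seed", range(5))
    def test_objective_nonincreasing_and_memberships_normalized(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(120, 4)) * rng.uniform(0.5, 3.0, size=4)
        res = fcm_cluster(X, c=3, seed=seed)
        trace = res.objective_trace
        assert all(a >= b - 1e-9 * abs(a) for a, b in zip(trace, trace[1:]))
        np.testing.assert_allclose(res.memberships.sum(axis=1), 1.0, atol=1e-9)

    def test_invalid_inputs(self, rng):
        X = rng.normal(size=(5, 2))
        with pytest.raises(ValueError):
            fcm_cluster(X, c=6)
        with pytest.raises(ValueError):
            fcm_cluster(np.array([[np.nan, 1.0]]), c=1)
        with pytest.raises(ValueError):
            fcm_cluster(X, c=2, m=1.0)


class TestFISEvaluation:
    def _single_rule_model(self):
        return FISModel(
            centers=np.array([[0.0, 0.0]]),
            widths=np.array([[1.0, 1.0]]),
            coefs=np.array([[2.0, -1.0]]),
            intercepts=np.array([5.0]),
            input_names=["a", "b"],
            scaler_mean=np.zeros(2),
            scaler_scale=np.ones(2),
        )

    def test_single_rule_is_its_consequent(self):
        model = self._single_rule_model()
        x = np.array([1.5, 2.0])
        assert evaluate_fis(model, x) == pytest.approx(2.0 * 1.5 - 1.0 * 2.0 + 5.0, abs=1e-12)

    def test_symmetric_rules_average(self):
        model = FISModel(
            centers=np.array([[-1.0], [1.0]]),
            widths=np.array([[1.0], [1.0]]),
            coefs=np.array([[0.0], [0.0]]),
            intercepts=np.array([10.0, 20.0]),
            input_names=["x"],
            scaler_mean=np.zeros(1),
            scaler_scale=np.ones(1),
        )
        # at the midpoint both rules fire equally
        assert evaluate_fis(model, np.array([0.0])) == pytest.approx(15.0, abs=1e-12)

    def test_batch_equals_loop(self, rng):
        X = rng.normal(size=(500, 1))
        y = np.sin(X[:, 0])
        model = fit_anfis(X, y, TrainConfig(n_rules=3, epochs=5, seed=0))
        Xq = rng.normal(size=(20, 1))
        batch = model.predict(Xq)
        loop = np.array([evaluate_fis(model, x) for x in Xq])
        np.testing.assert_array_equal(batch, loop)

    def test_far_input_finite(self, rng):
        X = rng.normal(size=(100, 2))
        y = X.sum(axis=1)
        model = fit_anfis(X, y, TrainConfig(n_rules=3, epochs=2, seed=0))
        out = model.predict(np.array([[1e6, -1e6]]))
        assert np.isfinite(out).all()


class TestTraining:
    def test_single_rule_reduces_to_ols(self, rng):
        X = rng.normal(size=(300, 4))
        y = X @ np.array([1.0, -2.0, 0.5, 3.0]) + 7 + rng.normal(0, 0.5, 300)
        model = fit_anfis(X, y, TrainConfig(n_rules=1, epochs=3, seed=0))
        np.testing.assert_allclose(
            model.predict(X), _ols_predictions(X, y, X), atol=1e-8
        )

    def test_two_regime_recovery(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(-2, 2, size=(800, 1))
        y = np.where(x[:, 0] < 0, 1 + 2 * x[:, 0], 1 - 3 * x[:, 0])
        model = fit_anfis(x, y, TrainConfig(n_rules=2, epochs=50, seed=0))
        r = np.corrcoef(y, model.predict(x))[0, 1]
        assert r >= 0.99

    def test_epochs_zero_returns_unchanged(self, rng):
        X = rng.normal(size=(100, 2))
        y = X.sum(axis=1)
        from ipfpvol.anfis import fcm_cluster, init_fis_from_fcm

        fcm = fcm_cluster(X, c=2, seed=0)
        model = init_fis_from_fcm(X, y, fcm)
        before = model.predict(X).copy()
        trained = train_hybrid(model, X, y, TrainConfig(n_rules=2, epochs=0))
        np.testing.assert_array_equal(trained.predict(X), before)

    def test_noiseless_linear_exact_after_lse(self, rng):
        X = rng.normal(size=(400, 3))
        y = X @ np.array([2.0, -1.0, 4.0]) + 10
        model = fit_anfis(X, y, TrainConfig(n_rules=3, epochs=1, seed=1))
        rmse = np.sqrt(np.mean((model.predict(X) - y) ** 2))
        assert rmse < 1e-6

    @pytest.mark.parametrize("seed", range(3))
    def test_training_rmse_improves(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(300, 2))
        y = np.sin(X[:, 0]) * 3 + X[:, 1] ** 2 + rng.normal(0, 0.1, 300)
        from ipfpvol.anfis import fcm_cluster, init_fis_from_fcm, _rmse

        cfg = TrainConfig(n_rules=3, epochs=30, seed=seed)
        fcm = fcm_cluster(X, c=3, seed=seed)
        model = init_fis_from_fcm(X, y, fcm)
        before = _rmse(model, X, y)
        trained = train_hybrid(model, X, y, cfg)
        assert _rmse(trained, X, y) <= before + 1e-12

    def test_widths_positive(self, rng):
        X = rng.normal(size=(200, 3))
        y = X.sum(axis=1) + rng.normal(0, 0.1, 200)
        model = fit_anfis(X, y, TrainConfig(n_rules=4, epochs=20, seed=0))
        assert (model.widths > 0).all()

    def test_normalization_equivariance(self, rng):
        X = rng.normal(size=(300, 3))
        y = X @ np.array([5.0, 1.0, -2.0]) + rng.normal(0, 0.2, 300)
        scale = np.array([1000.0, 0.01, 3.0])
        shift = np.array([50.0, -7.0, 0.0])
        cfg = TrainConfig(n_rules=2, epochs=20, seed=0)
        m_raw = fit_anfis(X, y, cfg)
        m_scaled = fit_anfis(X * scale + shift, y, cfg)
        np.testing.assert_allclose(
            m_scaled.predict(X * scale + shift), m_raw.predict(X), rtol=1e-6
        )

    def test_parameter_recovery_planted_ts_model(self):
        # data from a known 2-rule TS model with small noise
        rng = np.random.default_rng(7)
        X = rng.uniform(-3, 3, size=(1000, 1))
        w1 = np.exp(-0.5 * ((X[:, 0] + 1.5) / 1.0) ** 2)
        w2 = np.exp(-0.5 * ((X[:, 0] - 1.5) / 1.0) ** 2)
        y_true = (w1 * (2 * X[:, 0] + 1) + w2 * (-X[:, 0] + 4)) / (w1 + w2)
        y = y_true + rng.normal(0, 0.01, 1000)
        tr, te = np.arange(0, 800), np.arange(800, 1000)
        model = fit_anfis(X[tr], y[tr], TrainConfig(n_rules=2, epochs=50, seed=0))
        r = np.corrcoef(y_true[te], model.predict(X[te]))[0, 1]
        assert r >= 0.99


class TestSerialization:
    def test_json_round_trip_bit_identical(self, tmp_path, rng):
        X = rng.normal(size=(200, 3))
        y = X.sum(axis=1) + rng.normal(0, 0.3, 200)
        model = fit_anfis(X, y, TrainConfig(n_rules=3, epochs=10, seed=0))
        path = tmp_path / "model.json"
        model.to_json(path)
        back = FISModel.from_json(path)
        Xq = rng.normal(size=(1000, 3))
        np.testing.assert_array_equal(model.predict(Xq), back.predict(Xq))

    def test_dimension_mismatch_rejected(self, rng):
        X = rng.normal(size=(50, 2))
        y = X.sum(axis=1)
        model = fit_anfis(X, y, TrainConfig(n_rules=1, epochs=1, seed=0))
        with pytest.raises(ValueError):
            model.predict(np.ones((3, 5)))
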