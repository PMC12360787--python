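"""Sequence-regressor tests: architecture accounting, training, inference."""

import numpy as np
import pytest

from dcs2l.datagen import TrainingSet
from dcs2l.forward_models import InvalidParameterError
from dcs2l.regressor import (
    LstmRegressor,
    RegressorConfig,
    TrainedRegressor,
    build_regressor,
    parameter_count,
    predict_cbfi,
    train_regressor,
)


@pytest.fixture(scope="module")
def toy_dataset(lags):
    """Noiseless synthetic mapping: decay rate of a scaled curve → label."""
    rng = np.random.default_rng(0)
    n = 240
    labels = rng.uniform(2.0, 40.0, n).astype(np.float32)
    tau_c = 2.0e-4 / labels  # faster decay for larger label
    curves = 1.0 + 0.5 * np.exp(-2 * lags[None, :] / tau_c[:, None])
    return TrainingSet(inputs=curves, labels=labels, lags=lags)


@pytest.fixture(scope="module")
def tiny_config():
    return RegressorConfig(hidden_layers=2, hidden_units=16, dropout=0.0,
                           learning_rate=5e-3, batch_size=64, epochs=150, seed=2)


class TestParameterAccounting:
    def test_reference_architecture_count(self):
        assert parameter_count(RegressorConfig()) == 198_273

    def test_minimal_architecture_count(self):
        # one layer, one unit: 4·(1·2+1)=12 gate weights + 2 head weights
        assert parameter_count(RegressorConfig(hidden_layers=1, hidden_units=1)) == 14

    def test_count_independent_of_sequence_length(self):
        a = parameter_count(RegressorConfig(input_size=31))
        b = parameter_count(RegressorConfig(input_size=62))
        assert a == b

    def test_built_model_matches_formula(self):
        for L, H in [(1, 4), (2, 8), (3, 16)]:
            model, count = build_regressor(RegressorConfig(hidden_layers=L, hidden_units=H))
            assert model.n_parameters == count == parameter_count(
                RegressorConfig(hidden_layers=L, hidden_units=H))


class TestGradients:
    def test_bptt_matches_finite_differences(self):
        cfg = RegressorConfig(hidden_layers=2, hidden_units=3, input_size=5,
                              dropout=0.0, seed=1)
        model = LstmRegressor(cfg, dtype=np.float64)
        X = np.random.default_rng(0).random((4, 5)) * 0.5 + 1.0
        y = np.array([1.0, 2.0, 3.0, 4.0])
        pred, cache = model._forward(X)
        grads = model._backward(2 * (pred - y) / 4, cache)
        rng = np.random.default_rng(9)
        for k, p in model.params.items():
            flat = list(np.ndindex(p.shape))
            picks = rng.choice(len(flat), size=min(3, len(flat)), replace=False)
            for i in [flat[j] for j in picks]:
                eps, orig = 1e-6, p[i]
                p[i] = orig + eps
                lp = np.mean((model._forward(X)[0] - y) ** 2)
                p[i] = orig - eps
                lm = np.mean((model._forward(X)[0] - y) ** 2)
                p[i] = orig
                fd = (lp - lm) / (2 * eps)
                assert grads[k][i] == pytest.approx(fd, rel=1e-4, abs=1e-9)


class TestTraining:
    def test_constant_label_dataset_converges_to_constant(self, lags):
        rng = np.random.default_rng(1)
        X = 1.0 + 0.5 * rng.random((120, 31)).astype(np.float32)
        ts = TrainingSet(inputs=X, labels=np.full(120, 7.0, dtype=np.float32), lags=lags)
        cfg = RegressorConfig(hidden_layers=1, hidden_units=8, dropout=0.0,
                              learning_rate=5e-3, batch_size=32, epochs=60, seed=3)
        trained = train_regressor(ts, cfg)
        preds = trained.model.predict_scaled(X[:10])
        np.testing.assert_allclose(preds, 7.0, rtol=0.05)

    def test_learns_decay_rate_mapping(self, toy_dataset, tiny_config):
        trained = train_regressor(toy_dataset, tiny_config)
        assert trained.loss_history["val"][-1] < trained.loss_history["val"][0] / 10
        pred = trained.model.predict_scaled(toy_dataset.inputs)
        rel = np.abs(pred - toy_dataset.labels) / toy_dataset.labels
        assert np.median(rel) < 0.15

    def test_loss_history_reproducible_across_runs(self, toy_dataset):
        cfg = RegressorConfig(hidden_layers=1, hidden_units=8, dropout=0.2,
                              learning_rate=5e-3, batch_size=64, epochs=5, seed=12)
        a = train_regressor(toy_dataset, cfg)
        b = train_regressor(toy_dataset, cfg)
        np.testing.assert_allclose(a.loss_history["train"], b.loss_history["train"],
                                   rtol=1e-6)

    def test_monotone_response_to_generating_flow(self, toy_dataset, tiny_config):
        """Predicted CBFi must increase with the generating decay rate."""
        from scipy.stats import spearmanr

        trained = train_regressor(toy_dataset, tiny_config)
        labels = np.linspace(3.0, 38.0, 10).astype(np.float32)
        tau_c = 2.0e-4 / labels
        lags = toy_dataset.lags
        curves = 1.0 + 0.5 * np.exp(-2 * lags[None, :] / tau_c[:, None])
        preds = trained.model.predict_scaled(curves)
        rho, _ = spearmanr(labels, preds)
        assert rho == pytest.approx(1.0)


class TestInference:
    def test_prediction_is_pure_function(self, toy_dataset, tiny_config):
        trained = train_regressor(toy_dataset, tiny_config)
        x = toy_dataset.inputs[:1]
        np.testing.assert_array_equal(predict_cbfi(trained, x), predict_cbfi(trained, x))

    def test_label_scale_division(self, toy_dataset, tiny_config):
        trained = train_regressor(toy_dataset, tiny_config)
        raw = trained.model.predict_scaled(toy_dataset.inputs[:4])
        cbfi = predict_cbfi(trained, toy_dataset.inputs[:4])
        np.testing.assert_allclose(cbfi, raw / 1e6, rtol=1e-6)

    def test_wrong_lag_count_rejected(self, toy_dataset, tiny_config):
        trained = train_regressor(toy_dataset, tiny_config)
        with pytest.raises(InvalidParameterError):
            predict_cbfi(trained, np.ones((2, 17)))

    def test_negative_outputs_clamped_with_warning(self, tiny_config):
        model = LstmRegressor(tiny_config)
        model.out_shift = -50.0  # force negative raw outputs
        with pytest.warns(UserWarning):
            out = predict_cbfi(model, np.ones((3, 31)) * 1.2)
        assert np.all(out == 0.0)
        assert model.warn_negative == 3

    def test_save_load_roundtrip_preserves_predictions(self, toy_dataset, tiny_config,
                                                       tmp_path):
        trained = train_regressor(toy_dataset, tiny_config)
        path = tmp_path / "model.dcs2l"
        trained.save(path)
        back = TrainedRegressor.load(path)
        np.testing.assert_allclose(predict_cbfi(back, toy_dataset.inputs[:8]),
                                   predict_cbfi(trained, toy_dataset.inputs[:8]),
                                   rtol=1e-6)
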