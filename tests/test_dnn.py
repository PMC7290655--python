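"""The seven-layer classifier: activations, training, search, transfer."""

import numpy as np
import pytest

from gpspbs.dnn import (
    DNNConfig,
    TrainedModel,
    fine_tune,
    hyperparameter_search,
    predict_proba,
    relu,
    sigmoid,
    train_dnn,
)
from gpspbs.evaluation import roc_auc


class TestActivations:
    @pytest.mark.parametrize("x,expected", [(2.0, 2.0), (-3.0, 0.0), (0.0, 0.0)])
    def test_relu(self, x, expected):
        assert relu(x) == expected

    def test_relu_vectorized(self):
        assert np.array_equal(relu(np.array([-1.0, 0.5])), [0.0, 0.5])

    def test_sigmoid_at_zero_is_half(self):
        assert sigmoid(0.0) == 0.5


class TestConfig:
    def test_exactly_five_hidden_layers_required(self):
        with pytest.raises(ValueError):
            DNNConfig(hidden_layer_sizes=(32, 16, 8, 4))
        with pytest.raises(ValueError):
            DNNConfig(hidden_layer_sizes=(64, 32, 16, 8, 4, 2))

    @pytest.mark.parametrize("kwargs", [
        {"dropout_ratio": 1.0}, {"momentum": 1.0}, {"batch_size": 0},
        {"l2_strength": -1.0}, {"output_units": 3},
    ])
    def test_range_validation(self, kwargs):
        with pytest.raises(ValueError):
            DNNConfig(**kwargs)

    def test_parameter_count(self):
        cfg = DNNConfig(hidden_layer_sizes=(2, 2, 2, 2, 2), output_units=1)
        # (3*2+2) + 4*(2*2+2) + (2*1+1)
        assert cfg.parameter_count(3) == 8 + 24 + 3


@pytest.fixture(scope="module")
def quick_config():
    return DNNConfig(hidden_layer_sizes=(32, 16, 8, 8, 4), epochs=60,
                     dropout_ratio=0.1, seed=3)


class TestTraining:
    def test_separable_clusters_reach_high_training_auc(
            self, small_gaussian_data, quick_config):
        X, y = small_gaussian_data
        model = train_dnn(X, y, quick_config)
        auc, _ = roc_auc(model.predict_proba(X), y)
        assert auc >= 0.99

    def test_scores_in_open_unit_interval(self, small_gaussian_data, quick_config):
        X, y = small_gaussian_data
        model = train_dnn(X, y, quick_config)
        p = model.predict_proba(X)
        assert np.all((p > 0) & (p < 1))

    def test_same_seed_identical_models(self, small_gaussian_data, quick_config):
        X, y = small_gaussian_data
        a = train_dnn(X, y, quick_config)
        b = train_dnn(X, y, quick_config)
        for wa, wb in zip(a.weights, b.weights):
            assert np.array_equal(wa, wb)

    def test_batch_equals_single_item_prediction(self, small_gaussian_data,
                                                 quick_config):
        X, y = small_gaussian_data
        model = train_dnn(X, y, quick_config)
        batch = model.predict_proba(X[:10])
        single = np.array([model.predict_proba(X[i:i + 1])[0] for i in range(10)])
        assert np.allclose(batch, single)  # dropout is off at inference

    def test_single_class_rejected(self, quick_config):
        X = np.zeros((10, 5))
        with pytest.raises(ValueError):
            train_dnn(X, np.ones(10, int), quick_config)

    def test_width_mismatch_rejected(self, small_gaussian_data, quick_config):
        X, y = small_gaussian_data
        model = train_dnn(X, y, quick_config)
        with pytest.raises(ValueError):
            model.predict_proba(np.zeros((3, 7)))

    def test_serialization_roundtrip(self, tmp_path, small_gaussian_data,
                                     quick_config):
        X, y = small_gaussian_data
        model = train_dnn(X, y, quick_config)
        path = tmp_path / "model.json"
        model.save(path)
        back = TrainedModel.load(path)
        assert np.allclose(back.predict_proba(X[:5]), model.predict_proba(X[:5]))


class TestFineTune:
    def test_zero_epochs_is_identity(self, small_gaussian_data, quick_config):
        X, y = small_gaussian_data
        parent = train_dnn(X, y, quick_config)
        child = fine_tune(parent, X[:20], y[:20], epochs=0)
        assert np.array_equal(child.predict_proba(X), parent.predict_proba(X))
        assert child.parent_model is parent

    def test_reduced_learning_rate(self, small_gaussian_data, quick_config):
        X, y = small_gaussian_data
        parent = train_dnn(X, y, quick_config)
        child = fine_tune(parent, X, y, epochs=1, lr_scale=0.1)
        assert child.config.learning_rate == pytest.approx(
            0.1 * parent.config.learning_rate)

    def test_three_level_chain_bookkeeping(self, small_gaussian_data,
                                           quick_config):
        X, y = small_gaussian_data
        group = train_dnn(X, y, quick_config)
        family = fine_tune(group, X, y, epochs=1)
        cluster = fine_tune(family, X, y, epochs=1)
        assert cluster.parent_model is family
        assert cluster.parent_model.parent_model is group

    def test_width_mismatch_rejected(self, small_gaussian_data, quick_config):
        X, y = small_gaussian_data
        parent = train_dnn(X, y, quick_config)
        with pytest.raises(ValueError):
            fine_tune(parent, np.zeros((4, 7)), np.array([0, 1, 0, 1]))


class TestHyperparameterSearch:
    def test_singleton_grid(self, small_gaussian_data, quick_config):
        X, y = small_gaussian_data
        best, auc = hyperparameter_search(X, y, [quick_config], folds=4)
        assert best is quick_config
        assert 0.0 <= auc <= 1.0

    def test_degenerate_learning_rate_loses(self, small_gaussian_data):
        X, y = small_gaussian_data
        sane = DNNConfig(hidden_layer_sizes=(16, 8, 8, 4, 4), epochs=40,
                         dropout_ratio=0.0, seed=1)
        frozen = DNNConfig(hidden_layer_sizes=(16, 8, 8, 4, 4), epochs=40,
                           dropout_ratio=0.0, seed=1, learning_rate=0.0,
                           patience=0)
        best, _ = hyperparameter_search(X, y, [frozen, sane], folds=4)
        assert best is sane
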