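import numpy as np
import pytest
from sklearn.linear_model import LogisticRegression

from m6amnet.model import BaseClassifierSpec
from m6amnet.simulate import SyntheticSpec, generate_synthetic_dataset, pwm_from_consensus


def tiny_spec(**overrides) -> BaseClassifierSpec:
    """Desk-scale base classifier used across training tests."""
    defaults = dict(
        attention_heads=2,
        attention_model_dim=16,
        conv1_filters=8,
        conv1_kernel=5,
        conv2_filters=8,
        conv2_kernel=3,
        pool_size=2,
        lstm_hidden=8,
        branch_fc_dim=8,
        head_fc_dims=(16, 2),
        dropout_rates=(0.2, 0.2),
        learning_rate=3e-3,
        batch_size=64,
        max_epochs=10,
        patience=5,
        seed=0,
    )
    defaults.update(overrides)
    return BaseClassifierSpec(**defaults)


@pytest.fixture
def tiny_model_spec():
    return tiny_spec()


@pytest.fixture(scope="session")
def strong_signal_dataset():
    """Near-separable synthetic data: every positive carries a 6-mer."""
    spec = SyntheticSpec(n_per_class=150, signal_strength=1.0,
                         motif=pwm_from_consensus("GGACGU"), motif_offset=3,
                         n_chromosomes=4, seed=123)
    return generate_synthetic_dataset(spec)


@pytest.fixture(scope="session")
def null_dataset():
    spec = SyntheticSpec(n_per_class=150, signal_strength=0.0, seed=321)
    return generate_synthetic_dataset(spec)


class FlattenedLogistic:
    """Cheap recipe satisfying the evaluation-module protocol."""

    def __init__(self, model):
        self._model = model

    def predict_proba(self, X):
        X = np.asarray(X)
        return self._model.predict_proba(X.reshape(len(X), -1))


def logistic_recipe(X, y, seed=0):
    model = LogisticRegression(max_iter=500, random_state=seed)
    model.fit(np.asarray(X).reshape(len(X), -1), y)
    return FlattenedLogistic(model)


@pytest.fixture
def recipe():
    return logistic_recipe
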