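import numpy as np
import pytest

from seatsom import (GeneratorConfig, PressureMapReducer, TrainConfig,
                     generate_dataset)


@pytest.fixture(scope="session")
def small_dataset():
    """72 frames, 12 per class, fixed seed."""
    return generate_dataset(12, rng_seed=7)


@pytest.fixture(scope="session")
def small_features(small_dataset):
    """Pooled-basis 256-element features and labels for the small dataset."""
    reducer = PressureMapReducer(mode="pooled").fit(small_dataset)
    X = reducer.transform(small_dataset)
    y = [f.label for f in small_dataset]
    return X, y


@pytest.fixture(scope="session")
def fast_config():
    """Shortened training schedule for unit tests."""
    return TrainConfig(max_iters=1500, n_restarts=2, seed=11)


@pytest.fixture(scope="session")
def trained(small_features, fast_config):
    from seatsom.som import assign_labels, train

    X, y = small_features
    model = train(X, fast_config)
    assign_labels(model, X, y)
    return model
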