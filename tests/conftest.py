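import numpy as np
import pytest

from uqseg import GeneratorParams, ModelConfig, build_model, generate_dataset


@pytest.fixture(scope="session")
def tiny_dataset():
    """12 samples of 32x32, 2/3 positive; shared read-only across tests."""
    params = GeneratorParams(
        n_samples=12, positive_fraction=2 / 3, image_size=32,
        lesion_radius_range=(4.0, 8.0), seed=11,
    )
    return generate_dataset(params)


@pytest.fixture(scope="session")
def mc_model():
    """Untrained depth-2 model with dropout in both paths."""
    return build_model(
        ModelConfig(depth=2, base_channels=8, dropout_placement="both", dropout_rate=0.5),
        seed=0,
    )


@pytest.fixture(scope="session")
def det_model():
    """Untrained depth-2 model without any dropout layers."""
    return build_model(
        ModelConfig(depth=2, base_channels=8, dropout_placement="none"), seed=0
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
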