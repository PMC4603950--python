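import numpy as np
import pytest

from facebmi.experiment import BMIExperiment, ExperimentSettings
from facebmi.synthetic import SyntheticConfig, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_config():
    """A desk-size generator configuration shared by the slower tests."""
    return SyntheticConfig(
        n_subjects=48, seed=11, image_size=48, template_points=30
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate_dataset(small_config, images=True)


@pytest.fixture(scope="session")
def small_settings():
    return ExperimentSettings(
        k=5,
        n_repeats=2,
        master_seed=5,
        inner_k=4,
        inner_repeats=1,
        lambda_grid=(0.0, 1.0, 100.0),
        sigma_grid=(1e-3, 1e-2),
        C_grid=(1.0, 100.0),
        downsample=2,
    )


@pytest.fixture(scope="session")
def small_results(small_dataset, small_settings):
    """One full seven-model run on the small dataset, shared across tests."""
    exp = BMIExperiment.from_synthetic(small_dataset, small_settings)
    return exp.run()
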