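import numpy as np
import pytest

from hervex import synthdata


@pytest.fixture(scope="session")
def small_config():
    """3 families x 6 short elements, no duplicates/fragments, fixed seed."""
    return synthdata.SimulationConfig(
        n_families=3,
        elements_per_family=6,
        element_length_range=(200, 400),
        duplication_rate=0.0,
        fragment_rate=0.0,
        baseline_mean_log2=(5.0, 1.0),
        seed=101,
    )


@pytest.fixture(scope="session")
def small_library(small_config):
    library, truth = synthdata.generate_library(small_config)
    return library, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
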