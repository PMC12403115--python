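import numpy as np
import pytest

from phenometrics import SpeciesConfig, default_config, generate_woodland


def logistic(t, t0, k):
    return 1.0 / (1.0 + np.exp(-k * (t - t0)))


@pytest.fixture(scope="session")
def small_oak_config():
    """A 12-oak woodland, default noise."""
    return default_config(
        rng_seed=11, species=[SpeciesConfig("oak", 12, 112.0, 7, 30.0)]
    )


@pytest.fixture(scope="session")
def small_woodland(small_oak_config):
    return generate_woodland(small_oak_config)
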