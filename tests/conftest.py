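import warnings

import numpy as np
import pytest

from adawin import SimConfig, preprocess_stream, simulate

# the zero-denominator metric warning is expected on hard grid points
warnings.filterwarnings("ignore", message="zero denominator")


@pytest.fixture(scope="session")
def short_sim():
    """A 600 s default-condition stream with its label track (seeded)."""
    return simulate(SimConfig(duration_s=600.0, seed=42))


@pytest.fixture(scope="session")
def short_clean(short_sim):
    stream, track = short_sim
    return preprocess_stream(stream), track


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
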