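import numpy as np
import pytest
from hypothesis import settings

import betaharmonics as bh

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def harmonic_recording():
    """5-min nonsinusoidal-alpha scenario (2nd harmonic in the beta band)."""
    ts, truth = bh.gen_scenario(bh.make_scenario("harmonic", seed=0))
    return ts, truth


@pytest.fixture(scope="session")
def independent_recording():
    """5-min sinusoidal alpha + independent genuine beta scenario."""
    ts, truth = bh.gen_scenario(bh.make_scenario("independent", seed=0))
    return ts, truth


@pytest.fixture(scope="session")
def anticorrelated_recording():
    ts, truth = bh.gen_scenario(bh.make_scenario("anticorrelated", seed=0))
    return ts, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
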