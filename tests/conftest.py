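import numpy as np
import pytest

import standreflex as sr


@pytest.fixture(scope="session")
def model():
    return sr.build_plant()


@pytest.fixture(scope="session")
def muscles():
    return sr.default_muscles()


@pytest.fixture(scope="session")
def short_cfg():
    """Short episode configuration for fast end-to-end checks."""
    return sr.EpisodeConfig(t_total=8.0, horizon=6.0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
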