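import numpy as np
import pytest

import vsd_spacetime as vs


@pytest.fixture(scope="session")
def hex7():
    return vs.build_hex_geometry(7, 0.1)


@pytest.fixture(scope="session")
def hex61():
    return vs.build_hex_geometry(61, 0.18)


@pytest.fixture(scope="session")
def hex169():
    return vs.build_hex_geometry(169, 0.18)


@pytest.fixture(scope="session")
def small_dataset(hex61):
    """Default study conditions at reduced scale (61 channels, 8 trials)."""
    return vs.compose_dataset(hex61, n_trials=8, seed=7)


@pytest.fixture(scope="session")
def small_deriv(small_dataset):
    """Filtered derivative field of the stationary-bar condition."""
    _, deriv = vs.preprocess(
        small_dataset.recordings["stationary_bar"], small_dataset.blank
    )
    return deriv


@pytest.fixture(scope="session")
def small_classification(small_deriv):
    return vs.classify(small_deriv)


@pytest.fixture()
def rng():
    """Fresh deterministic generator per test."""
    return np.random.default_rng(20260924)
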