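import warnings

import numpy as np
import pytest

from mweeg.simulate import GeneratorConfig, generate_session


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    """Pipeline functions warn on exclusions/degeneracies; keep test output clean."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield


@pytest.fixture(scope="session")
def small_config():
    """A fast session: short recording, few channels, artifacts off."""
    return GeneratorConfig(n_subjects=3, n_sections=6, montage=("Fz", "Pz", "O1"),
                           artifact_rate=0.0, seed=7)


@pytest.fixture(scope="session")
def small_session(small_config):
    return generate_session(small_config, 0)


@pytest.fixture(scope="session")
def default_session():
    """One full-size session under the default study design."""
    return generate_session(GeneratorConfig(seed=5), 0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
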