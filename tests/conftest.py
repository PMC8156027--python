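import numpy as np
import pytest

from skinnertank.stimuli import build_stimulus_set


@pytest.fixture(scope="session")
def small_set():
    """A 2v3 pair set shared across tests (generation is deterministic)."""
    return build_stimulus_set("2v3", seed=101)


@pytest.fixture(scope="session")
def sparse_set():
    """A 3v12 pair set (no area band)."""
    return build_stimulus_set("3v12", seed=102)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
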