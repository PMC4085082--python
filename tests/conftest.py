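import numpy as np
import pytest

from hierbeat import beats_from_recordings, simulate_dataset


@pytest.fixture(scope="session")
def small_split():
    """3 train + 3 test synthetic recordings at generator defaults (fixed seed)."""
    return simulate_dataset(n_recordings=6, n_beats=250, seed=11)


@pytest.fixture(scope="session")
def small_train_beats(small_split):
    return beats_from_recordings(small_split[0])


@pytest.fixture(scope="session")
def small_test_beats(small_split):
    return beats_from_recordings(small_split[1])


@pytest.fixture
def rng():
    return np.random.default_rng(42)
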