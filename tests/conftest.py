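import warnings

import numpy as np
import pytest

import coopaffect as ca


@pytest.fixture(autouse=True)
def _quiet_fit_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield


@pytest.fixture(scope="session")
def small_dataset():
    """4 labeled + 2 test speakers, 60 s sequences (shared, read-only)."""
    return ca.generate_dataset(1, n_labeled=4, n_test=2, duration=60.0)


@pytest.fixture(scope="session")
def trained_pool(small_dataset):
    """Pool with the 4 labeled speakers ingested (read-only)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        return ca.build_pool(small_dataset)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
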