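import numpy as np
import pytest

import linescan as ls


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def ds_path(tmp_path):
    """Factory for dataset bundle paths inside the test's tmp dir."""
    counter = {"n": 0}

    def make(name=None):
        counter["n"] += 1
        return str(tmp_path / (name or f"ds{counter['n']}"))

    return make


@pytest.fixture
def small_dataset(ds_path, rng):
    stack = rng.integers(0, 100, size=(12, 10, 8)).astype(np.uint16)
    return ls.Dataset([[stack]], ds_path()), stack
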