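import numpy as np
import pytest

from firethresh import WorldSpec


@pytest.fixture
def tiny_spec():
    """A 2x2 single-year reanalysis-like world."""
    return WorldSpec(n_lat=2, n_lon=2, years=(2003,), steps_per_day=24, seed=7)


@pytest.fixture
def small_spec():
    """A 4x4 three-year world used for pipeline-level tests."""
    return WorldSpec(n_lat=4, n_lon=4, years=(2003, 2004, 2005), steps_per_day=8, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
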