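import numpy as np
import pytest

from nirselect import SyntheticSpec, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_spec():
    """Reduced scenario for fast module tests (80 samples, 200 points)."""
    return SyntheticSpec(n_samples=80, n_points=200)


@pytest.fixture(scope="session")
def small_dataset(small_spec):
    return generate_dataset(small_spec, seed=7)
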