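import numpy as np
import pytest

from lirype import simulate


@pytest.fixture(scope="session")
def small_study():
    """A small but complete simulated study shared by read-only tests."""
    return simulate.simulate_study(
        n_regions=3, transects_per_region=4, n_years=8, seed=101
    )


@pytest.fixture(scope="session")
def medium_study():
    """Moderate design for tests that need more detections."""
    return simulate.simulate_study(
        n_regions=5, transects_per_region=8, n_years=10, seed=202
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
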