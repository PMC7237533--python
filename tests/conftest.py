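import numpy as np
import pytest

from crittorque.fixtures import FIXTURES, get_fixture, sample_fixture_battery


@pytest.fixture(scope="session")
def baseline_params():
    return get_fixture("baseline")


@pytest.fixture(scope="session", params=sorted(FIXTURES))
def any_fixture_params(request):
    return get_fixture(request.param)


@pytest.fixture(scope="session")
def small_battery():
    """A handful of random parameter vectors from the validated region."""
    return sample_fixture_battery(5, seed=42)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
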