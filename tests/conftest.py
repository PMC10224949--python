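import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")

from outlierlift import make_condition


@pytest.fixture(scope="session")
def std_spec():
    """Standard same-color condition."""
    return make_condition("same_color")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
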