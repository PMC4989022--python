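import numpy as np
import pytest
from hypothesis import settings

from fattaste import study1_series, study2_series

# keep property tests reproducible in any environment
settings.register_profile("ci", derandomize=True, max_examples=200)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def series9():
    """Nine-level study-1 oleic-acid ladder (0.0088 %w/v bottom)."""
    return study1_series()


@pytest.fixture(scope="session")
def series12():
    """Twelve-level study-2 oleic-acid ladder (0.0028 %w/v bottom)."""
    return study2_series()


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
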