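import numpy as np
import pytest

from multimutation import (
    USA_FEMALE,
    USA_MALE,
    USA_MALE_FEMALE,
)


@pytest.fixture(scope="session")
def mf_params():
    """Pooled male+female USA first-admission fit (the twin-analysis curve)."""
    return USA_MALE_FEMALE


@pytest.fixture(scope="session")
def male_params():
    return USA_MALE


@pytest.fixture(scope="session")
def female_params():
    return USA_FEMALE


@pytest.fixture(scope="session")
def age_grid():
    return np.linspace(0.0, 80.0, 161)
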