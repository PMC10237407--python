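import pytest

from gliosched import (
    DEFAULT_PARAMS,
    standard_schedule,
    tid_uniform_schedule,
    trial_schedule,
)
from gliosched.optimizer import SimSettings


@pytest.fixture(scope="session")
def params():
    return DEFAULT_PARAMS


@pytest.fixture(scope="session")
def trial():
    """The clinically evaluated course: 7 x 3.96 Gy QD + 9 x 1.0 Gy TID."""
    return trial_schedule()


@pytest.fixture(scope="session")
def standard():
    """The 35 Gy / 10 fx reference course."""
    return standard_schedule()


@pytest.fixture(scope="session")
def tid_only():
    """The dose-relaxed uniform TID comparator (30 fx over 10 weekdays)."""
    return tid_uniform_schedule()


@pytest.fixture(scope="session")
def sim():
    return SimSettings()
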