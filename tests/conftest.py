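import datetime as dt

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from pre2dup import GlobalParams, ParameterSpace
from pre2dup.datasets import load_example_history, load_example_parameters


@pytest.fixture(scope="session")
def glob():
    return GlobalParams()


@pytest.fixture(scope="session")
def empty_space():
    """Global defaults only: no ATC or package entries."""
    return ParameterSpace()


@pytest.fixture(scope="session")
def example_space():
    return load_example_parameters()


@pytest.fixture(scope="session")
def example_purchases():
    """Five 10-DDD purchases at gaps 10/5/15/10 days (stockpiling)."""
    return load_example_history()
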