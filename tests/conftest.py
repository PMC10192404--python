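import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from picturesort import (
    SyntheticConfig,
    default_dialects,
    default_registry,
    default_scales,
    default_standards,
    generate_cohort,
)

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def dialects():
    return default_dialects()


@pytest.fixture(scope="session")
def standards():
    return default_standards()


@pytest.fixture(scope="session")
def scales():
    return default_scales()


@pytest.fixture(scope="session")
def cohort():
    """Feasibility-sized synthetic cohort (25 children, 18 adults)."""
    return generate_cohort(SyntheticConfig(seed=7))


@pytest.fixture()
def child_records(dialects):
    """One child subject x timepoint answering three items."""
    return pd.DataFrame(
        {
            "subject_id": "C1",
            "role": "child",
            "timepoint": "baseline",
            "item_id": ["apple", "soda", "squash"],
            "response": ["once a day", "sometimes", "never"],
        }
    )
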