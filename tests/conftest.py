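import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the test-only oracles

from urbanrhythm import activity, synthetic


@pytest.fixture(scope="session")
def small_dataset():
    """A small five-city synthetic study: two weeks, 120 users per city."""
    config = synthetic.small_config(users_per_city=120, days=(1, 14), seed=7)
    return synthetic.generate_dataset(config)


@pytest.fixture(scope="session")
def small_calls(small_dataset):
    """Calls of the small study with activity-day columns attached."""
    calls = small_dataset.calls.join(
        activity.assign_activity_days(small_dataset.calls["start"])
    )
    calls["city"] = calls["caller_id"].str.split("_").str[0]
    return calls
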