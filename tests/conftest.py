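import pytest
from hypothesis import settings

from renalcea import baseline_config

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def baseline():
    """Fresh packaged base-case config (provider perspective active)."""
    return baseline_config()


@pytest.fixture
def baseline_societal():
    return baseline_config("SOCIETAL")


@pytest.fixture
def baseline_with_events(baseline):
    """Base case with the one-time event-cost layer switched on."""
    baseline.conventions.include_event_costs = True
    return baseline
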