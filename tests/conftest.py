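from datetime import datetime, timedelta

import pytest
from hypothesis import HealthCheck, settings

# deterministic, CI-friendly hypothesis runs
settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

LIGHTS_OFF = datetime(2000, 1, 1, 21, 30)


@pytest.fixture
def lights_off():
    return LIGHTS_OFF


def make_hypnogram(stages, lights_off=LIGHTS_OFF):
    """Build a Hypnogram30 with consistent lights-on for the given stages."""
    from actiscore import Hypnogram30

    return Hypnogram30(
        stages=tuple(stages),
        lights_off=lights_off,
        lights_on=lights_off + timedelta(seconds=30 * len(stages)),
    )


@pytest.fixture
def hypnogram_factory():
    return make_hypnogram
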