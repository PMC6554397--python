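import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture()
def assay_geometry():
    """The 500 x 90 um attachment-assay channel, 1 cm long."""
    from colonyflow.geometry import ChannelGeometry

    return ChannelGeometry.from_lab_units(1.0, 500.0, 90.0)


@pytest.fixture()
def shallow_geometry():
    """The shallow 500 x 25 um colonization channel, 1 cm long."""
    from colonyflow.geometry import ChannelGeometry

    return ChannelGeometry.from_lab_units(1.0, 500.0, 25.0)
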