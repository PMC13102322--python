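import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from nm3.simulate import worked_example  # noqa: E402
from nm3.events import write_actions, write_events, write_exposures  # noqa: E402


@pytest.fixture(scope="session")
def reference_quarter():
    """The deterministic reference worked-example collections."""
    return worked_example()


@pytest.fixture()
def reference_csvs(reference_quarter, tmp_path):
    """The worked example written out as the three CSV interchange files."""
    events, exposures, actions = reference_quarter
    paths = {
        "events": tmp_path / "events.csv",
        "exposures": tmp_path / "exposures.csv",
        "actions": tmp_path / "actions.csv",
    }
    write_events(events, paths["events"])
    write_exposures(exposures, paths["exposures"])
    write_actions(actions, paths["actions"])
    return paths
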