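import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from b1web import SimulationConfig, default_scenario, run_scenario

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_run():
    """Full-season integration of the mid-cube default scenario."""
    return run_scenario(default_scenario())


@pytest.fixture(scope="session")
def quick_config():
    """Coarse-step config for tests that only need qualitative dynamics."""
    return SimulationConfig(dt=0.1)
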