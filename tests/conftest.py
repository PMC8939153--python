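import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from myoarm.config import default_config

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

DEG = np.pi / 180.0


@pytest.fixture(scope="session")
def cfg():
    """Default muscle-mode configuration with auto-calibrated slack lengths."""
    return default_config()


@pytest.fixture(scope="session")
def cfg_torque(cfg):
    from dataclasses import replace

    return replace(cfg, actuation=replace(cfg.actuation, mode="torque"))
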