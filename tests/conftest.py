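import dataclasses

import pytest
from hypothesis import HealthCheck, settings

from poddry.config import RunConfig, simulate

settings.register_profile(
    "default", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_cfg() -> RunConfig:
    return RunConfig()


def _mode_cfg(cfg: RunConfig, mode: str) -> RunConfig:
    return dataclasses.replace(cfg, geometry=dataclasses.replace(cfg.geometry, mode=mode))


@pytest.fixture(scope="session")
def two_component_result(default_cfg):
    """Full 1230-min two-component reference run at packaged defaults."""
    return simulate(default_cfg)


@pytest.fixture(scope="session")
def shell_only_result(default_cfg):
    return simulate(_mode_cfg(default_cfg, "shell_only"))


@pytest.fixture(scope="session")
def kernel_only_result(default_cfg):
    return simulate(_mode_cfg(default_cfg, "kernel_only"))
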