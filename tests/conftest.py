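import pytest
from hypothesis import settings

from metalsense import load_sensor_registry, packaged_registry_path

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def registry():
    return load_sensor_registry(packaged_registry_path())


@pytest.fixture(scope="session")
def by_name(registry):
    return {s.name: s for s in registry}
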