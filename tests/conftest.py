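import pytest
from hypothesis import HealthCheck, settings

from dnasga.codes import build_code, load_registry

settings.register_profile(
    "package",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("package")


@pytest.fixture(scope="session")
def registry():
    return load_registry()


@pytest.fixture(scope="session")
def codes(registry):
    """All 15 presets built once per session."""
    return {key: build_code(entry) for key, entry in registry.items()}


@pytest.fixture(scope="session")
def small_keys(registry):
    """Keys of the (63, 57, 3) presets."""
    return [k for k, e in registry.items() if k != "MDH"]
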