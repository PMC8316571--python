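import pytest

from otolithct.phantom import default_config, generate_phantom, silence


@pytest.fixture(scope="session")
def quiet_phantom():
    """Zero-noise default phantom: every compartment at exactly its mean HU."""
    return generate_phantom(silence(default_config(0)))


@pytest.fixture(scope="session")
def noisy_phantom():
    """Default phantom with the published per-material HU noise (fixed seed)."""
    return generate_phantom(default_config(7))
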