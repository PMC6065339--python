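import dataclasses

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from cladodem.config import default_config  # noqa: E402


@pytest.fixture(scope="session")
def small_config():
    """A scaled-down campaign for fast structural tests."""
    base = default_config(7)
    return dataclasses.replace(
        base,
        n_plants={"female": 10, "hermaphrodite": 20, "male": 10},
        n_flowering_plants={"female": 15, "hermaphrodite": 30, "male": 15},
        n_shrink_attached={"female": 8, "hermaphrodite": 10, "male": 8},
        n_shrink_detached={"female": 10, "hermaphrodite": 10, "male": 10},
        n_clonality={"female": 12, "hermaphrodite": 12, "male": 12},
    )


@pytest.fixture(scope="session")
def small_bundle(small_config):
    from cladodem.simulate import simulate_population

    return simulate_population(small_config)
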