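import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_dataset():
    """120 planted-rule molecules with energies, shared across read-only tests."""
    from fpbow.synthetic import SyntheticConfig, generate

    ds, dock = generate(SyntheticConfig(n_molecules=120, active_fraction=0.3, seed=99))
    return ds, dock
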