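import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_pair():
    """A small deterministic sample pair shared across tests."""
    from cgpval import SimulationConfig, simulate_sample_pair

    cfg = SimulationConfig(
        n_somatic_snv=60,
        n_somatic_indel=10,
        n_germline=25,
        n_msi_loci=20,
        seed=7,
    )
    return simulate_sample_pair(cfg, seed=7)
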