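import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def toy_simref():
    """A small simulated reference with genes, decoy and gene sets."""
    from oxisoma.synthetic_data import SimulationConfig, simulate_reference

    cfg = SimulationConfig(seed=5, genome_length=12_000, n_genes=20,
                           duplicated_region=(400, 1.0))
    return simulate_reference(cfg)
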