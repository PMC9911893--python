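import pytest
from hypothesis import settings

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_params():
    """A compact two-WGD genome for pipeline-level tests."""
    from wgdkit.simulate import SimulationParams, WgdEvent

    return SimulationParams(
        n_chromosomes=3,
        genes_per_chromosome=150,
        wgd_events=(WgdEvent(0.27, 0.3, 0.5), WgdEvent(0.97, 0.2, 0.5)),
        seed=7,
    )


@pytest.fixture(scope="session")
def small_dataset(small_params):
    from wgdkit.simulate import simulate_genome

    return simulate_genome(small_params)
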