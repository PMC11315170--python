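import numpy as np
import pytest

from paraloscope.synthetic_data import SimBundle, SimulationConfig, simulate


@pytest.fixture(scope="session")
def default_bundle() -> SimBundle:
    """One default-condition simulated study, shared across tests."""
    return simulate(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def easy_bundle() -> SimBundle:
    """A small, low-divergence, unfragmented study (fast, near-exact regime)."""
    return simulate(
        SimulationConfig(
            n_taxa=4,
            root_genes=3,
            dup_rate=0.0,
            loss_rate=0.0,
            subst_scale=0.2,
            fragmentation=0.0,
            seed=5,
        )
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
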