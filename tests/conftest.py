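import numpy as np
import pytest

from irdosim import interface


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def sim_results():
    """One full desk-scale simulation workflow shared by the acceptance
    checks: air and water runs at 3e6 / 8e6 histories."""
    cfg = interface.SimulationConfig(
        air_histories=3_000_000,
        water_histories=8_000_000,
        seed=20260,
        batches=12,
    )
    dataset, manifest = interface.run_simulation_workflow(cfg)
    return dataset, manifest
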