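import numpy as np
import pytest

from mnpool.model import PoolConfig, run_simulation
from mnpool.synthetic import RenewalSpec, gen_renewal_trains


@pytest.fixture(scope="session")
def small_pool_result():
    """A 25-MN simulation with constant drives spanning the tonic range
    (recurrent inhibition on), shared across model-level tests."""
    C = np.linspace(0.03, 0.09, 25)
    cfg = PoolConfig(n_mn=25, duration=10.0, C=C, seed=7)
    return run_simulation(cfg, compute_force=False)


@pytest.fixture(scope="session")
def renewal_set():
    """30 synthetic gamma-renewal units, 30 s at the reference rate spread."""
    return gen_renewal_trains(RenewalSpec(n_units=30, seed=42))
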