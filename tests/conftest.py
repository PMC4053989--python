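import numpy as np
import pytest

from crmkit.simulate import SimConfig, simulate_benchmark


@pytest.fixture(scope="session")
def small_benchmark():
    """Training-fragment benchmark only (tiny gene universe to keep it fast)."""
    return simulate_benchmark(SimConfig(seed=0, n_genes=10, n_target_genes=2))


@pytest.fixture(scope="session")
def full_benchmark():
    """Default study conditions: 14/25 fragments, 1000 genes, 150 targets."""
    return simulate_benchmark(SimConfig(seed=3))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
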