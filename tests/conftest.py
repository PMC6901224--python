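import numpy as np
import pytest

from deepmaldi import MzGrid, SimConfig
from deepmaldi.simulate import simulate_pool, simulate_reference_sample


@pytest.fixture(scope="session")
def small_grid():
    """3-9 kDa at 1 Da: big enough for noise windows, fast to simulate."""
    return MzGrid.uniform(3000.0, 9000.0, 1.0)


@pytest.fixture(scope="session")
def small_config(small_grid):
    return SimConfig(grid=small_grid, n_peaks=20, amp_range=(50.0, 1.0e4),
                     noise_sigma=1.0, jitter_scale=0.0, seed=101)


@pytest.fixture(scope="session")
def small_truth(small_config):
    return simulate_reference_sample(small_config)


@pytest.fixture(scope="session")
def aligned_pool(small_truth, small_grid):
    """Jitter-free pool: members already on the common grid."""
    pool = simulate_pool(small_truth, small_grid, 64, seed=202)
    for s in pool:
        s.aligned = True
    return pool


def make_isolated_gaussian(grid, center, amplitude, sigma):
    return amplitude * np.exp(-0.5 * ((grid.mz - center) / sigma) ** 2)
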