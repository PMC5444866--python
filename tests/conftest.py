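import numpy as np
import pytest

from oscgp import OUoscParams, OUParams, TimeSeries, sample_gp
from oscgp.gp import FitConfig


@pytest.fixture(scope="session")
def grid_25h():
    """30-minute sampling over 25 hours (51 points)."""
    return np.arange(0.0, 25.01, 0.5)


@pytest.fixture(scope="session")
def ou_series(grid_25h):
    return sample_gp(OUParams(alpha=0.5, sigma=1.0), grid_25h, 0.1, 1, seed=11)[0]


@pytest.fixture(scope="session")
def ouosc_series(grid_25h):
    return sample_gp(OUoscParams(alpha=0.2, beta=0.5, sigma=1.0), grid_25h, 0.1, 1, seed=7)[0]


@pytest.fixture()
def fast_fit_config():
    return FitConfig(restarts=3, seed=0, noise_mode="fixed", sigma_n_sq=0.1)


def random_instance(seed, n):
    """Small random GP instance for oracle comparisons."""
    rng = np.random.default_rng(seed)
    t = np.sort(rng.uniform(0.0, 10.0, n))
    while np.any(np.diff(t) <= 1e-6):
        t = np.sort(rng.uniform(0.0, 10.0, n))
    y = rng.normal(0.0, 1.0, n)
    return TimeSeries(t, y, cell_id=f"rand{seed}")
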