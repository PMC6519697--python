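import numpy as np
import pytest

from reverb.simulation import simulate_network, simulate_population
from reverb.types import BranchingParams

# Matched-model parameters of the reference configuration:
# N=10^4, kappa=4, dt=4 ms, 50 sampled units, per-unit rate 7.25 Hz.
REV = BranchingParams(m=0.98, h=5.8, N=10_000, n=50, L=300_000, seed=42)
AI = BranchingParams(m=0.0, h=290.0, N=10_000, n=50, L=100_000, seed=42)


@pytest.fixture(scope="session")
def rev_run():
    """Reverberating network run (m=0.98), 300k bins, with sampled raster."""
    return simulate_network(REV)


@pytest.fixture(scope="session")
def rev_counts(rev_run):
    return rev_run.sampled_counts


@pytest.fixture(scope="session")
def ai_run():
    """Asynchronous-irregular network run (m=0), 100k bins."""
    return simulate_network(AI)


@pytest.fixture(scope="session")
def pop_m09():
    """Fully sampled population trace at m=0.9, 500k bins."""
    params = BranchingParams(m=0.9, h=29.0, N=10_000, n=50, L=500_000, seed=7)
    return simulate_population(params)


def batch_se(x: np.ndarray, n_batches: int = 100) -> float:
    """Standard error of the mean of a correlated series via batch means."""
    n = (x.size // n_batches) * n_batches
    means = x[:n].reshape(n_batches, -1).mean(axis=1)
    return float(means.std(ddof=1) / np.sqrt(n_batches))
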