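import numpy as np
import pytest

from msvolt.core import MSVParams
from msvolt.synthetic import SimulationSpec, simulate_msv, default_benchmark_params


@pytest.fixture(scope="session")
def bench_params() -> MSVParams:
    return default_benchmark_params(3)


@pytest.fixture(scope="session")
def small_msv_data(bench_params):
    """A small simulated dataset shared by cheap tests (J=3, 30 × 150)."""
    spec = SimulationSpec(n_channels=3, n_events=30, samples_per_event=150,
                          params=bench_params, seed=123)
    return simulate_msv(spec)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20259)
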