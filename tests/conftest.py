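import numpy as np
import pytest

from prefulvent import PhantomParams, analyze_series, synthesize_series


@pytest.fixture(scope="session")
def small_params() -> PhantomParams:
    """Noiseless motion-free phantom on a 64-grid (fast shared fixture)."""
    return PhantomParams(grid_size=64, seed=42)


@pytest.fixture(scope="session")
def small_phantom(small_params):
    return synthesize_series(small_params)


@pytest.fixture(scope="session")
def default_phantom():
    """Noiseless phantom at the full 128-grid acquisition geometry."""
    return synthesize_series(PhantomParams(seed=7))


@pytest.fixture(scope="session")
def analyzed_small(small_phantom):
    series, truth = small_phantom
    return analyze_series(series, truth.lung_mask), truth


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
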