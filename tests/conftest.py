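import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from strawspec import SpectralDataset, WavelengthGrid

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def vis_grid():
    return WavelengthGrid(np.arange(500.0, 980.0, 2.0))


@pytest.fixture
def small_grid():
    return WavelengthGrid(np.linspace(500.0, 538.0, 20))


@pytest.fixture
def dataset_factory():
    """Small random datasets with a linear SSC signal in one channel."""

    def make(n=12, p=20, seed=0, variety="white"):
        rng = np.random.default_rng(seed)
        grid = WavelengthGrid(500.0 + 2.0 * np.arange(p))
        ssc = rng.uniform(7.0, 13.0, size=n)
        X = rng.normal(0.0, 0.01, size=(n, p))
        X[:, p // 2] += 0.05 * ssc
        return SpectralDataset(
            wavelengths=grid,
            absorbance=X,
            ssc=ssc,
            variety=[variety] * n,
            sample_id=[f"{variety}-{i}" for i in range(n)],
        )

    return make
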