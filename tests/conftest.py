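import numpy as np
import pytest

from proximpute.synth import SimConfig, gen_region, simulate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(20250923)


@pytest.fixture(scope="session")
def small_dataset():
    """A seeded 387-unit two-phase dataset at the default scenario."""
    cfg = SimConfig(n=387, seed=42)
    return simulate_dataset(cfg, np.random.default_rng(42))


@pytest.fixture(scope="session")
def region():
    """A 12-county grid region (192 tracts) with stores and adjacency."""
    return gen_region(n_counties=12, tracts_per_county=16, n_stores=40,
                      rng=np.random.default_rng(7))
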