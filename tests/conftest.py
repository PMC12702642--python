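import numpy as np
import pytest

from chromounmix import (
    KIDNEY_WEIGHTS_HEALTHY,
    SyntheticScenario,
    WavelengthGrid,
    generate_cohort,
    make_default_library,
)
from chromounmix.synthetic_data import scale_weights_physical


@pytest.fixture(scope="session")
def default_grid():
    return WavelengthGrid.default()


@pytest.fixture(scope="session")
def default_library(default_grid):
    return make_default_library(default_grid)


@pytest.fixture(scope="session")
def physical_healthy_weights(default_library):
    """Healthy-kidney weight profile rescaled so mu_a * d peaks at 0.9."""
    return scale_weights_physical(
        KIDNEY_WEIGHTS_HEALTHY, default_library, thickness_cm=0.05
    )


@pytest.fixture
def noiseless_cohort(default_library, physical_healthy_weights):
    scenario = SyntheticScenario(
        seed=7, true_weights=physical_healthy_weights, n_samples=3, noise_sd=0.0
    )
    samples, truth = generate_cohort(scenario, default_library)
    return samples, truth


def rng_spectrum(grid, seed, scale=10.0):
    """Random non-negative absorption values on a grid."""
    rng = np.random.default_rng(seed)
    return rng.uniform(0.0, scale, size=len(grid))
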