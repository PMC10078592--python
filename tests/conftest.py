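import numpy as np
import pytest
from hypothesis import settings

import ppscr

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20240517)


@pytest.fixture
def unit_habitat():
    """10 x 10 km habitat tiled by 100 unit windows, no covariates."""
    return ppscr.build_grid((0.0, 0.0, 10.0, 10.0), 1.0)


@pytest.fixture
def habitat_with_cov(rng):
    """10 x 10 km habitat with one Uniform(-1, 1) covariate."""
    cov = rng.uniform(-1, 1, size=(100, 1))
    return ppscr.build_grid(
        (0.0, 0.0, 10.0, 10.0), 1.0, covariates=cov, covariate_names=("hcov0",)
    )


@pytest.fixture
def detgrid_with_cov(rng):
    """8 x 8 km detection region inside the habitat, one covariate."""
    cov = rng.uniform(-1, 1, size=(16, 1))
    return ppscr.build_grid(
        (1.0, 1.0, 9.0, 9.0), 2.0, covariates=cov, covariate_names=("dcov0",),
        role="detection",
    )


@pytest.fixture
def sim3_dataset():
    """One synthetic dataset from the 36-habitat-window / 64-detection-window
    design (N = 100 fixed)."""
    scenario = ppscr.preset("sim3", habitat_resolution=2.0, detection_resolution=1.0,
                            seed=42)
    return ppscr.simulate_dataset(scenario)
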