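import math

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from lenscount import LensSimParams, sample_epithelium
from lenscount.pipeline import AnalysisConfig, simulate_lens_stacks

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def small_lens_params(**overrides) -> LensSimParams:
    """A 0.8 mm lens at the same surface density as the full-size default."""
    base = dict(
        lens_radius=400.0,
        n_epithelial=4500,
        n_meridional=900,
        n_fiber=400,
        eq_fov_y=(-170.0, 230.0),
        seed=11,
    )
    base.update(overrides)
    return LensSimParams(**base)


@pytest.fixture(scope="session")
def small_params():
    return small_lens_params()


@pytest.fixture(scope="session")
def small_gt(small_params):
    return sample_epithelium(small_params)


@pytest.fixture(scope="session")
def small_lens_run(small_params):
    """One simulated small lens: (ground truth, stacks, view azimuth)."""
    psi = math.radians(210.0)
    gt, stacks = simulate_lens_stacks(small_params, view_azimuth=psi)
    return gt, stacks, psi


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
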