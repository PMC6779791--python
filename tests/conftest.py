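import numpy as np
import pytest

from dynalff import SimulationConfig, simulate_cohort
from dynalff.cohort import BoldRun


TINY_CONFIG = dict(
    n_per_group=12,
    grid_shape=(10, 10, 10),
    voxel_size_mm=3.0,
    tr_s=2.0,
    n_volumes=120,
    effect_center_vox=(5, 5, 5),
    effect_radius_vox=2.0,
    modulation_depth=0.9,
    duration_coupling=0.0,
    mod_freq_hz=0.008,
    noise_sd=0.25,
)


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small, strong-effect cohort for fast end-to-end tests."""
    return simulate_cohort(SimulationConfig(**TINY_CONFIG, seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def single_voxel_run(series: np.ndarray, tr_s: float = 2.0) -> BoldRun:
    """Wrap a 1-D series into a 1-voxel BoldRun."""
    data = np.asarray(series, dtype=float).reshape(1, 1, 1, -1)
    return BoldRun(data, tr_s, np.eye(4), np.ones((1, 1, 1), dtype=bool))
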