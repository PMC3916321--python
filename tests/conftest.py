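import numpy as np
import pytest

from rehokit.io import Scan4D
from rehokit.synthetic import SimConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20240131)


@pytest.fixture
def small_scan(rng):
    """Random 6x6x6x40 scan on a 3-mm grid, TR 3 s."""
    affine = np.diag([3.0, 3.0, 3.0, 1.0])
    return Scan4D(data=rng.standard_normal((6, 6, 6, 40)), affine=affine, tr_s=3.0)


@pytest.fixture
def tiny_sim_config():
    """Fast simulation preset for unit tests (not the study conditions)."""
    from rehokit.synthetic import RoiSpec

    return SimConfig(
        grid_shape=(16, 16, 16),
        n_volumes=60,
        n_per_group=3,
        roi_specs=[RoiSpec(center_voxel=(8, 8, 8), radius_mm=6.0, label="roi_a")],
        seed=7,
    )
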