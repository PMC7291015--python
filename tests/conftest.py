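import numpy as np
import pytest

from digispindle import make_phase_preset, simulate_geometry, simulate_trajectories
from digispindle.models import AcquisitionSpec, CometModel, GeometryModel, OpticsModel


@pytest.fixture(scope="session")
def metaphase_preset():
    return make_phase_preset("metaphase")


@pytest.fixture(scope="session")
def desk_cell(metaphase_preset):
    """One desk-scale metaphase cell: (config, geometry, trajectories)."""
    geometry = simulate_geometry(metaphase_preset, 101)
    trajectories = simulate_trajectories(metaphase_preset, geometry, 202)
    return metaphase_preset, geometry, trajectories


@pytest.fixture()
def fine_acquisition():
    """Isotropic 0.05 µm pitch grid for PSF-calibration measurements."""
    return AcquisitionSpec(
        n_frames=2, voxel_pitch_um=(0.05, 0.05, 0.05), fov_extent_um=(4.0, 4.0, 4.0)
    )


@pytest.fixture()
def clean_optics():
    return OpticsModel(background_level=0.0, bleach_rate_per_s=0.0)


@pytest.fixture()
def default_comet():
    return CometModel()


def stationary_trajectory(xyz, n_frames=2, start=0, traj_id=0):
    from digispindle.models import GroundTruthTrajectory

    pos = np.tile(np.asarray(xyz, dtype=float), (n_frames, 1))
    return GroundTruthTrajectory(traj_id, start, pos, 0.0)
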