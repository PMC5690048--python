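import numpy as np
import pytest

from voxadapt.dose import BeamSetup, DoseInfluence, compute_dij
from voxadapt.fluence import ConstraintSet
from voxadapt.grid import Structure, StructureSet, VoxelGrid
from voxadapt.phantoms import make_phantom_2d


def single_voxel_problem(d_value=None, constraints=None):
    """One voxel, one beamlet, D = [[1]]: dose equals the weight."""
    from scipy import sparse

    grid = VoxelGrid((1, 1, 1))
    mask = np.ones((1, 1, 1), dtype=bool)
    structures = StructureSet(
        grid,
        [Structure("body", mask, "body"), Structure("target", mask, "target", dpres=70.0)],
    )
    dij = DoseInfluence(sparse.csr_matrix(np.array([[1.0]])), grid_shape=grid.shape)
    return structures, dij


@pytest.fixture(scope="session")
def small_phantom():
    """Small 2D phantom with a circular target and one abutting OAR."""
    return make_phantom_2d(
        size=48,
        spacing_mm=2.5,
        target_radius_mm=10.0,
        inner_target_radius_mm=None,
        target_offset_mm=(0.0, 0.0),
        oar_spec=[{"name": "oar", "angle_deg": 270, "gap_mm": 2.5, "radius_mm": 7.0}],
        seed=3,
    )


@pytest.fixture(scope="session")
def small_dij(small_phantom):
    return compute_dij(small_phantom, BeamSetup(gantry_angles=(0.0, 120.0, 240.0)))


@pytest.fixture(scope="session")
def small_constraints():
    return ConstraintSet.from_dict(
        {
            "ptv": {"d_max": 70.0, "p_max": 1500.0, "d_min": 70.0, "p_min": 4000.0},
            "oar": {"d_max": 15.0, "p_max": 300.0},
            "body": {"d_max": 25.0, "p_max": 8000.0},
        }
    )
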