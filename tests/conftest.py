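import numpy as np
import pytest

from dvhregistry.dvh_core import CumulativeDVH, DoseGrid, StructureMask
from dvhregistry.ingest import CANONICAL_ORGANS
from dvhregistry.registry import Registry
from dvhregistry.synthgen import StudyConfig, generate_cohorts


def dvh_from_voxels(doses, bin_width=0.1, volume_cc=10.0):
    """Build a cumulative DVH from a flat list of equal-volume voxel doses."""
    from dvhregistry.dvh_core import compute_cumulative_dvh

    arr = np.asarray(doses, dtype=float).reshape(1, 1, -1)
    grid = DoseGrid(arr, spacing=(10.0, 10.0, 10.0 * volume_cc / arr.size))
    mask = StructureMask("voxels", np.ones(arr.shape, dtype=bool))
    return compute_cumulative_dvh(grid, mask, bin_width)


@pytest.fixture
def piecewise_dvh():
    """The reference three-point curve (0 Gy, 100 %), (10, 50), (20, 0)."""
    return CumulativeDVH(
        np.array([0.0, 10.0, 20.0]), np.array([100.0, 50.0, 0.0]), 10.0
    )


@pytest.fixture(scope="session")
def study_plans():
    """One seeded default synthetic study (10 pre / 9 post plans, 10 organs)."""
    return generate_cohorts(StudyConfig(seed=20141201))


@pytest.fixture(scope="session")
def study_registry(study_plans):
    """The same study loaded into an in-memory registry with named cohorts."""
    pre, post = study_plans
    registry = Registry(":memory:")
    pre_serials = [registry.insert_plan(p) for p in pre]
    post_serials = [registry.insert_plan(p) for p in post]
    registry.define_cohort("preconstraints", pre_serials)
    registry.define_cohort("postconstraints", post_serials)
    yield registry
    registry.close()


@pytest.fixture(scope="session")
def all_organs():
    return CANONICAL_ORGANS
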