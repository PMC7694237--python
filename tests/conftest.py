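import numpy as np
import pytest

from dummyrun import BinaryMask, CohortConfig, DoseGrid, GridGeometry, generate_cohort
from dummyrun.pipeline import RunConfig, build_study_report

#: Seed of the default study cohort exercised end to end.
STUDY_SEED = 1701


def make_geometry(n=16, spacing=1.0, origin=(0.0, 0.0, 0.0)):
    return GridGeometry((n, n, n), (spacing,) * 3, origin)


def sphere_mask(geometry, center_vox, radius_vox):
    """Boolean sphere in voxel-index space."""
    grids = np.ogrid[tuple(slice(0, s) for s in geometry.shape)]
    r2 = sum((g - c) ** 2 for g, c in zip(grids, center_vox))
    return BinaryMask(geometry, r2 <= radius_vox**2)


def uniform_dose(geometry, value):
    return DoseGrid(geometry, np.full(geometry.shape, float(value)))


@pytest.fixture(scope="session")
def small_cohort():
    """Reduced cohort (8 institutions, 48^3 at 5 mm) for structural tests."""
    config = CohortConfig(
        n_institutions=8,
        n_imn_institutions=3,
        grid=GridGeometry((48, 48, 48), (5.0, 5.0, 5.0)),
        seed=11,
    )
    return generate_cohort(config)


@pytest.fixture(scope="session")
def small_report(small_cohort):
    return build_study_report(small_cohort, RunConfig())


@pytest.fixture(scope="session")
def study_cohort():
    """The default study conditions: 24 institutions, 6 with IMN, 96^3 at 2.5 mm."""
    return generate_cohort(CohortConfig(seed=STUDY_SEED))


@pytest.fixture(scope="session")
def study_report(study_cohort):
    return build_study_report(study_cohort, RunConfig())
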