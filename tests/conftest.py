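import numpy as np
import pytest

from dirqa.io_formats import StructureMask, VoxelGrid
from dirqa.pipeline import _loader_for, evaluate_cohort
from dirqa.synthetic_cohort import CohortConfig, simulate_cohort


def concentric_sphere_pair(r_inner=20.0, r_outer=25.0, spacing=(1.0, 1.0, 1.0)):
    """Two concentric voxelized spheres on one grid (analytic oracle pair)."""
    pad = 3.0
    shape = tuple(int(np.ceil(2 * (r_outer + pad) / s)) + 1 for s in spacing)
    grid = VoxelGrid(shape, spacing)
    c = np.array([(n - 1) * s / 2 for n, s in zip(shape, spacing)])
    ax = [np.arange(shape[i]) * spacing[i] for i in range(3)]
    d2 = (
        (ax[0][:, None, None] - c[0]) ** 2
        + (ax[1][None, :, None] - c[1]) ** 2
        + (ax[2][None, None, :] - c[2]) ** 2
    )
    inner = StructureMask(grid=grid, occupancy=d2 <= r_inner**2, label="inner")
    outer = StructureMask(grid=grid, occupancy=d2 <= r_outer**2, label="outer")
    return inner, outer


def random_mask_pair(rng, shape=(8, 8, 8), spacing=(1.0, 1.0, 1.0), p=0.35):
    """Random non-empty mask pair on a shared small grid."""
    grid = VoxelGrid(shape, spacing)
    while True:
        a = rng.random(shape) < p
        b = rng.random(shape) < p
        if a.any() and b.any():
            return (
                StructureMask(grid=grid, occupancy=a, label="a"),
                StructureMask(grid=grid, occupancy=b, label="b"),
            )


@pytest.fixture(scope="session")
def default_reduced_run():
    """One full default-design cohort (12 patients, 64³ grid) evaluated with
    projections; shared across tests that need population-scale output."""
    cfg = CohortConfig.reduced(master_seed=0)
    cohort = simulate_cohort(cfg)
    loader = _loader_for(cohort, cohort.manifest, None)
    ev = evaluate_cohort(cohort.manifest, loader, pixel_shape=(32, 32))
    return {"config": cfg, "cohort": cohort, "ev": ev}
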