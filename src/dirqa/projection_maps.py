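"""Population surface-distance projection images.

Spatial patterns of propagation error are visualised by projecting each
structure's surface deviations onto the three principal patient planes:

1. A tight bounding box along the patient directions (RL, AP, CC) is placed
   around the evaluated structure.
2. Every surface voxel's deviation (distance to the reference surface) is
   projected into the transversal (RL×AP), sagittal (AP×CC) and coronal
   (RL×CC) planes by dropping the plane-normal coordinate.
3. In each plane a grid with a fixed number of pixels spans the bounding
   box; deviations landing in the same pixel are averaged.  The fixed pixel
   count normalises away per-scan size differences so scans and patients
   can be stacked.
4. Across scans, the pixelwise 50th and 90th percentile of the scan-level
   means form the population map; maps are displayed with equal width and
   an aspect ratio matching the mean structure over all scans.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .geometry_metrics import SurfaceDistanceSet
from .io_formats import PATIENT_AXES, StructureMask

#: plane name -> (horizontal axis, vertical axis) patient directions
PLANE_AXES: dict[str, tuple[str, str]] = {
    "transversal": ("RL", "AP"),
    "sagittal": ("AP", "CC"),
    "coronal": ("RL", "CC"),
}
PLANES = tuple(PLANE_AXES)

DEFAULT_PIXEL_SHAPE = (64, 64)


@dataclasses.dataclass(frozen=True)
class BoundingBox:
    """Tight axis-aligned box (mm) around occupied voxel centres, in patient
    axis order (RL, AP, CC)."""

    mins: tuple[float, float, float]
    maxs: tuple[float, float, float]

    def __post_init__(self) -> None:
        if any(lo > hi for lo, hi in zip(self.mins, self.maxs)):
            raise ValueError("bounding box min exceeds max")

    @property
    def extents(self) -> np.ndarray:
        return np.asarray(self.maxs) - np.asarray(self.mins)

    def axis(self, role: str) -> int:
        return PATIENT_AXES.index(role)


@dataclasses.dataclass
class ProjectionGrid:
    """Per-scan plane image of averaged surface deviations on a fixed pixel grid."""

    plane: str
    mean_deviation: np.ndarray  # (nu, nv), NaN where no voxel projected
    count: np.ndarray  # (nu, nv) int
    labels: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.plane not in PLANE_AXES:
            raise ValueError(f"unknown plane {self.plane!r}")
        if self.mean_deviation.shape != self.count.shape:
            raise ValueError("mean_deviation and count must share a shape")

    @property
    def pixel_shape(self) -> tuple[int, int]:
        return self.mean_deviation.shape


@dataclasses.dataclass
class PopulationProjectionMap:
    """Pixelwise percentile of scan-level mean deviations over a population."""

    plane: str
    percentile: float
    values: np.ndarray  # (nu, nv) mm, NaN = missing
    n_contributing: np.ndarray  # scans contributing per pixel
    aspect_ratio: float = 1.0  # display height / width

    def __post_init__(self) -> None:
        if self.aspect_ratio <= 0:
            raise ValueError("aspect ratio must be positive")


def bounding_box(mask: StructureMask) -> BoundingBox:
    """Smallest box along the patient directions containing all occupied
    voxel centres."""
    if mask.is_empty:
        raise ValueError("bounding box of an empty mask is undefined")
    idx = np.argwhere(mask.occupancy)
    mm = mask.grid.voxel_centers_mm(idx)
    lo, hi = mm.min(axis=0), mm.max(axis=0)
    order = [mask.grid.axis_of(role) for role in PATIENT_AXES]
    return BoundingBox(tuple(lo[order]), tuple(hi[order]))


def _patient_coords(sds: SurfaceDistanceSet) -> np.ndarray:
    """Surface positions reordered to (RL, AP, CC) columns."""
    order = [sds.grid.axis_of(role) for role in PATIENT_AXES]
    return sds.positions[:, order]


def _pixel_index(coord: np.ndarray, lo: float, hi: float, n: int) -> np.ndarray:
    """Affine map of mm coordinates in [lo, hi] to pixel indices [0, n).

    Half-open binning: floor of the relative coordinate scaled by n, with the
    upper edge clamped into the last pixel.  A zero-extent axis maps
    everything to pixel 0.
    """
    extent = hi - lo
    if extent <= 0:
        return np.zeros(len(coord), dtype=np.intp)
    pix = np.floor((coord - lo) / extent * n).astype(np.intp)
    return np.clip(pix, 0, n - 1)


def project_deviations(
    sds: SurfaceDistanceSet,
    box: BoundingBox,
    pixel_shape: tuple[int, int] | Mapping[str, tuple[int, int]] = DEFAULT_PIXEL_SHAPE,
    labels: dict | None = None,
) -> dict[str, ProjectionGrid]:
    """Project surface deviations into all three patient planes.

    Every surface voxel contributes to exactly one pixel per plane; pixel
    values are the mean deviation of contributing voxels, so per grid
    ``sum(mean*count) == sum(deviations)`` exactly.
    """
    if len(sds) == 0:
        raise ValueError("cannot project an empty surface-distance set")
    coords = _patient_coords(sds)
    grids: dict[str, ProjectionGrid] = {}
    for plane, (u_role, v_role) in PLANE_AXES.items():
        shape = pixel_shape[plane] if isinstance(pixel_shape, Mapping) else pixel_shape
        nu, nv = int(shape[0]), int(shape[1])
        ua, va = box.axis(u_role), box.axis(v_role)
        iu = _pixel_index(coords[:, ua], box.mins[ua], box.maxs[ua], nu)
        iv = _pixel_index(coords[:, va], box.mins[va], box.maxs[va], nv)
        total = np.zeros((nu, nv))
        count = np.zeros((nu, nv), dtype=np.intp)
        np.add.at(total, (iu, iv), sds.distances)
        np.add.at(count, (iu, iv), 1)
        mean = np.full((nu, nv), np.nan)
        nz = count > 0
        mean[nz] = total[nz] / count[nz]
        grids[plane] = ProjectionGrid(plane, mean, count, labels=dict(labels or {}))
    return grids


def aggregate_population_map(
    grids: Sequence[ProjectionGrid],
    percentile: float,
    aspect_ratio: float = 1.0,
    min_scans: int = 1,
) -> PopulationProjectionMap:
    """Pixelwise percentile of scan-level mean deviations.

    Percentiles use linear interpolation between order statistics (midpoint
    median for even counts) over the scans where the pixel is defined;
    pixels defined in fewer than ``min_scans`` scans are missing.
    """
    if not grids:
        raise ValueError("cannot aggregate an empty grid list")
    plane = grids[0].plane
    shape = grids[0].pixel_shape
    for g in grids:
        if g.plane != plane or g.pixel_shape != shape:
            raise ValueError("all grids must share plane and pixel_shape")
    stack = np.stack([g.mean_deviation for g in grids])
    n_contrib = np.sum(~np.isnan(stack), axis=0)
    with np.errstate(all="ignore"):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            values = np.nanpercentile(stack, percentile, axis=0)
    values[n_contrib < min_scans] = np.nan
    return PopulationProjectionMap(plane, float(percentile), values, n_contrib, aspect_ratio)


def mean_structure_aspect(boxes: Sequence[BoundingBox]) -> dict[str, float]:
    """Per-plane display aspect (vertical/horizontal mean extent) of the mean
    structure over all scans of all patients."""
    if not boxes:
        raise ValueError("need at least one bounding box")
    mean_ext = np.mean([b.extents for b in boxes], axis=0)
    aspects = {}
    for plane, (u_role, v_role) in PLANE_AXES.items():
        u = mean_ext[PATIENT_AXES.index(u_role)]
        v = mean_ext[PATIENT_AXES.index(v_role)]
        aspects[plane] = float(v / u) if u > 0 else 1.0
    return aspects


def render_map(
    pmap: PopulationProjectionMap,
    path: str | Path,
    vmax: float | None = None,
    width_inches: float = 4.0,
    title: str | None = None,
) -> Path:
    """Render a population map as PNG: fixed width, height from the aspect
    ratio, viridis colour scale in mm, missing pixels hatched grey."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    path = Path(path)
    values = pmap.values
    masked = np.ma.masked_invalid(values.T)  # transpose: u horizontal, v vertical
    height = width_inches * pmap.aspect_ratio
    fig, ax = plt.subplots(figsize=(width_inches, max(height, 0.5) + 0.8))
    cmap = plt.get_cmap("viridis").copy()
    cmap.set_bad("0.85")
    im = ax.imshow(masked, origin="lower", cmap=cmap, vmin=0.0, vmax=vmax, aspect="auto", interpolation="nearest")
    fig.colorbar(im, ax=ax, label="surface deviation [mm]")
    ax.set_xticks([])
    ax.set_yticks([])
    if title:
        ax.set_title(title, fontsize=9)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def write_map_csv(pmap: PopulationProjectionMap, path: str | Path) -> Path:
    """Numeric sidecar: the raw pixel matrix (NaN = missing) for bit-exact
    inspection alongside the rendered PNG."""
    path = Path(path)
    np.savetxt(path, pmap.values, delimiter=",", fmt="%.17g")
    return path


def read_map_csv(path: str | Path) -> np.ndarray:
    return np.atleast_2d(np.loadtxt(path, delimiter=","))
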