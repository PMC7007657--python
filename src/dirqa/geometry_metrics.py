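"""Voxel-mask comparison metrics for contour-propagation accuracy.

Three metrics quantify how well an automatically propagated (or
re-delineated) structure agrees with the manual ground truth of the same
scan:

* **DSC** — Dice similarity coefficient, ``2|A∩B| / (|A|+|B|)``: overlap
  ratio, most informative for small structures.
* **MSD** — mean surface distance in mm: the average distance between the
  two structure surfaces, informative for large structures.
* **HD** — Hausdorff distance in mm: the largest surface-to-surface
  distance, a worst-case measure that is deliberately outlier-sensitive.

Surface voxels are occupied voxels with at least one face-adjacent
(6-connectivity) background or out-of-bounds neighbour.  Distances are
Euclidean between surface-voxel centres, with anisotropic spacing respected.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .io_formats import StructureMask, VoxelGrid

#: face-connectivity structuring element (6 neighbours)
_FACE_STRUCT = ndimage.generate_binary_structure(3, 1)
_FULL_STRUCT = ndimage.generate_binary_structure(3, 3)


class EmptyMaskError(ValueError):
    """Raised when an operation requires a non-empty mask."""


class MetricUndefinedError(ValueError):
    """Raised when a metric has no defined value (e.g. Dice of two empty masks)."""


class GridMismatchError(ValueError):
    """Raised when two masks under comparison live on different grids."""


@dataclasses.dataclass
class SurfaceDistanceSet:
    """Distances from each surface voxel of a structure to a reference surface.

    ``positions`` are mm coordinates (array-axis order) of the evaluated
    structure's surface-voxel centres; ``distances`` the nonnegative mm
    distance of each to the nearest reference surface-voxel centre.
    """

    positions: np.ndarray  # (n, 3) mm, array-axis order
    distances: np.ndarray  # (n,) mm
    grid: VoxelGrid
    labels: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        self.distances = np.asarray(self.distances, dtype=float)
        if len(self.positions) != len(self.distances):
            raise ValueError("positions and distances must have equal length")
        if np.any(self.distances < 0):
            raise ValueError("surface distances must be nonnegative")

    def __len__(self) -> int:
        return len(self.distances)


@dataclasses.dataclass
class TopologyReport:
    n_components: int
    euler_characteristic: int
    n_cavities: int
    n_handles: int

    @property
    def has_handle(self) -> bool:
        return self.n_handles > 0


@dataclasses.dataclass
class MetricRecord:
    """One (patient, scan, structure, arm) row of comparison metrics."""

    patient_id: str = ""
    scan_id: str = ""
    structure: str = ""
    arm: str = ""
    dsc: float = np.nan
    msd: float = np.nan
    hd: float = np.nan
    volume_test: float = np.nan
    volume_ref: float = np.nan
    status: str = "ok"


def volume(mask: StructureMask) -> float:
    """Structure volume in cm³ (occupied voxels × voxel volume)."""
    return mask.n_voxels * mask.grid.voxel_volume_mm3 / 1000.0


def dice(test: StructureMask, ref: StructureMask) -> float:
    """Dice similarity coefficient; symmetric; undefined for two empty masks."""
    _require_same_grid(test, ref)
    a, b = test.n_voxels, ref.n_voxels
    if a == 0 and b == 0:
        raise MetricUndefinedError("Dice is undefined for two empty masks")
    inter = int(np.count_nonzero(test.occupancy & ref.occupancy))
    return 2.0 * inter / (a + b)


def extract_surface(mask: StructureMask) -> np.ndarray:
    """Indices (n, 3) of surface voxels: occupied with a face-adjacent background
    or out-of-bounds neighbour (image boundary counts as background)."""
    if mask.is_empty:
        raise EmptyMaskError("cannot extract the surface of an empty mask")
    interior = ndimage.binary_erosion(mask.occupancy, structure=_FACE_STRUCT, border_value=0)
    return np.argwhere(mask.occupancy & ~interior)


def surface_distances(test: StructureMask, ref: StructureMask) -> SurfaceDistanceSet:
    """For each surface voxel of ``test``, the Euclidean mm distance to the
    nearest surface-voxel centre of ``ref`` (anisotropic spacing respected)."""
    _require_same_grid(test, ref)
    if test.is_empty or ref.is_empty:
        raise EmptyMaskError("surface distances require two non-empty masks")
    spacing = np.asarray(test.grid.spacing)
    origin = np.asarray(test.grid.origin)
    test_pts = extract_surface(test) * spacing + origin
    ref_pts = extract_surface(ref) * spacing + origin
    dists, _ = cKDTree(ref_pts).query(test_pts, workers=1)
    return SurfaceDistanceSet(
        positions=test_pts,
        distances=dists,
        grid=test.grid,
        labels={"test": test.label, "ref": ref.label},
    )


def mean_surface_distance(test: StructureMask, ref: StructureMask, mode: str = "symmetric") -> float:
    """Mean surface distance in mm.

    ``directed``: mean over the surface of ``test`` of the distance to ``ref``.
    ``symmetric`` (default): mean of the pooled distances of both directions.
    """
    if mode == "directed":
        return float(surface_distances(test, ref).distances.mean())
    if mode == "symmetric":
        d_tr = surface_distances(test, ref).distances
        d_rt = surface_distances(ref, test).distances
        return float(np.concatenate([d_tr, d_rt]).mean())
    raise ValueError(f"unknown MSD mode {mode!r}")


def hausdorff_distance(test: StructureMask, ref: StructureMask, percentile: float = 100.0) -> float:
    """Symmetric Hausdorff distance in mm: the larger of the two directed
    maxima.  ``percentile`` < 100 gives a percentile variant per direction
    (default 100 = classic worst case)."""
    d_tr = surface_distances(test, ref).distances
    d_rt = surface_distances(ref, test).distances
    if percentile >= 100.0:
        return float(max(d_tr.max(), d_rt.max()))
    return float(max(np.percentile(d_tr, percentile), np.percentile(d_rt, percentile)))


def check_topology(mask: StructureMask) -> TopologyReport:
    """Connected components, Euler characteristic and handle (genus) count.

    Foreground uses 6-connectivity, background the dual 26-connectivity.
    ``has_handle`` flags genus >= 1 ("pinhole"/donut structures), a known
    failure mode of deformable propagation for bladders overlapping the
    prostate.  Used to tag records, never to exclude them.
    """
    if mask.is_empty:
        raise EmptyMaskError("topology of an empty mask is undefined")
    from skimage.measure import euler_number

    occ = mask.occupancy
    n_comp = int(ndimage.label(occ, structure=_FACE_STRUCT)[1])
    chi = int(euler_number(occ, connectivity=1))
    # cavities: background components (26-conn) not connected to the border
    bg = np.pad(~occ, 1, constant_values=True)
    n_bg = int(ndimage.label(bg, structure=_FULL_STRUCT)[1])
    n_cav = n_bg - 1
    # chi = b0 - b1 + b2  =>  handles b1 = b0 + b2 - chi
    n_handles = n_comp + n_cav - chi
    return TopologyReport(n_comp, chi, n_cav, n_handles)


def compare_structures(
    test: StructureMask,
    ref: StructureMask,
    labels: dict | None = None,
    msd_mode: str = "symmetric",
    hd_percentile: float = 100.0,
    return_distances: bool = False,
) -> MetricRecord | tuple[MetricRecord, SurfaceDistanceSet | None]:
    """All metrics for one test/reference pair as a single record.

    Pairs with an empty mask yield a flagged failure record instead of an
    exception: failed propagations (e.g. collapsed bladders) are findings,
    not errors, and stay in the table.  With ``return_distances`` the
    test-to-reference surface-distance set is returned alongside (None on
    failure) so callers can reuse it, e.g. for projection maps.
    """
    labels = labels or {}
    rec = MetricRecord(
        patient_id=str(labels.get("patient_id", "")),
        scan_id=str(labels.get("scan_id", "")),
        structure=str(labels.get("structure", test.label)),
        arm=str(labels.get("arm", "")),
        volume_test=volume(test),
        volume_ref=volume(ref),
    )
    if test.is_empty or ref.is_empty:
        if test.is_empty and ref.is_empty:
            rec.status = "failed_both_empty"
        else:
            rec.status = "failed_empty_test" if test.is_empty else "failed_empty_ref"
            rec.dsc = 0.0
        return (rec, None) if return_distances else rec
    _require_same_grid(test, ref)
    rec.dsc = dice(test, ref)
    # one surface extraction and one KD-tree per mask, queried both ways
    spacing = np.asarray(test.grid.spacing)
    origin = np.asarray(test.grid.origin)
    pts_t = extract_surface(test) * spacing + origin
    pts_r = extract_surface(ref) * spacing + origin
    d_tr, _ = cKDTree(pts_r).query(pts_t, workers=1)
    d_rt, _ = cKDTree(pts_t).query(pts_r, workers=1)
    if msd_mode == "symmetric":
        rec.msd = float(np.concatenate([d_tr, d_rt]).mean())
    elif msd_mode == "directed":
        rec.msd = float(d_tr.mean())
    else:
        raise ValueError(f"unknown MSD mode {msd_mode!r}")
    if hd_percentile >= 100.0:
        rec.hd = float(max(d_tr.max(), d_rt.max()))
    else:
        rec.hd = float(max(np.percentile(d_tr, hd_percentile), np.percentile(d_rt, hd_percentile)))
    if return_distances:
        sds = SurfaceDistanceSet(positions=pts_t, distances=d_tr, grid=test.grid, labels=dict(labels))
        return rec, sds
    return rec


def _require_same_grid(test: StructureMask, ref: StructureMask) -> None:
    if not test.grid.same_geometry(ref.grid):
        raise GridMismatchError(
            f"masks live on different grids: {test.grid.shape}@{test.grid.spacing} vs "
            f"{ref.grid.shape}@{ref.grid.spacing}; resample first (io_formats.resample_to_grid)"
        )
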