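"""Mask, manifest and table I/O.

Structure delineations are exchanged as binary occupancy masks on regular,
possibly anisotropic voxel grids (NIfTI-1 primary, NRRD accepted).  A cohort
manifest (CSV) binds each mask file to its study role: ground truth,
CT-to-MR propagation, MR-to-MR propagation, or intra-observer re-delineation.

Conventions
-----------
* Voxel indices are 0-based; the centre of voxel ``(i, j, k)`` sits at
  ``origin + index * spacing`` (mm).
* Array axes map to patient directions via ``axis_roles``; the default is
  axis 0 = Right-Left (RL), axis 1 = Anterior-Posterior (AP),
  axis 2 = Cranio-Caudal (CC).  Roles are carried explicitly rather than
  inferred from NIfTI orientation matrices.
* All distances are millimetres; volumes are cm³ where stated.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

DEFAULT_AXIS_ROLES: tuple[str, str, str] = ("RL", "AP", "CC")
PATIENT_AXES = ("RL", "AP", "CC")

SCAN_IDS = ("pCT", "pMR", "MR10", "MR20", "MR30")
ROLES = ("ground_truth", "propagated_CT_MR", "propagated_MR_MR", "redelineation_IOV")
STRUCTURE_LABELS = (
    "prostate",
    "SV",
    "CTV56",
    "rectum",
    "bladder",
    "femhead_L",
    "femhead_R",
    "penile_bulb",
    "other",
)

MANIFEST_COLUMNS = ["patient_id", "scan_id", "structure", "role", "path"]


class MaskIOError(RuntimeError):
    """Raised for unreadable, non-3D or metadata-free mask volumes."""


class ManifestError(ValueError):
    """Raised when a cohort manifest violates its invariants."""


@dataclasses.dataclass(frozen=True)
class VoxelGrid:
    """Regular 3D voxel lattice with physical spacing and patient-axis roles."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis_roles: tuple[str, str, str] = DEFAULT_AXIS_ROLES

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(s) < 1 for s in self.shape):
            raise ValueError(f"shape must be three integers >= 1, got {self.shape}")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive on all axes, got {self.spacing}")
        if sorted(self.axis_roles) != sorted(PATIENT_AXES):
            raise ValueError(f"axis_roles must be a bijection onto {PATIENT_AXES}")
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(s) for s in self.origin))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def axis_of(self, role: str) -> int:
        """Array axis carrying the given patient direction (RL, AP or CC)."""
        return self.axis_roles.index(role)

    def voxel_centers_mm(self, indices: np.ndarray) -> np.ndarray:
        """Map an (n, 3) array of voxel indices to mm coordinates."""
        return np.asarray(self.origin) + np.asarray(indices, dtype=float) * np.asarray(self.spacing)

    def extent_mm(self) -> tuple[float, float, float]:
        """Physical size of the grid per axis (mm, outer voxel edges)."""
        return tuple(n * s for n, s in zip(self.shape, self.spacing))

    def same_geometry(self, other: "VoxelGrid", tol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and self.axis_roles == other.axis_roles
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
        )


@dataclasses.dataclass
class StructureMask:
    """Binary occupancy of one delineated structure on a voxel grid."""

    grid: VoxelGrid
    occupancy: np.ndarray
    label: str = "other"

    def __post_init__(self) -> None:
        occ = np.asarray(self.occupancy)
        if occ.ndim != 3:
            raise ValueError(f"occupancy must be 3D, got ndim={occ.ndim}")
        if tuple(occ.shape) != self.grid.shape:
            raise ValueError(f"occupancy shape {occ.shape} != grid shape {self.grid.shape}")
        if not self.label:
            raise ValueError("label must be non-empty")
        self.occupancy = occ.astype(bool)

    @property
    def n_voxels(self) -> int:
        return int(self.occupancy.sum())

    @property
    def is_empty(self) -> bool:
        return not self.occupancy.any()


def _affine_from_grid(grid: VoxelGrid) -> np.ndarray:
    aff = np.diag(list(grid.spacing) + [1.0])
    aff[:3, 3] = grid.origin
    return aff


def read_mask(
    path: str | Path,
    label: str = "other",
    axis_roles: tuple[str, str, str] = DEFAULT_AXIS_ROLES,
) -> StructureMask:
    """Read a volumetric file as a binary structure mask.

    Any nonzero voxel is occupied.  Spacing comes from the file header;
    patient-axis roles come from the caller (typically the manifest), not
    from orientation metadata.
    """
    path = Path(path)
    if not path.exists():
        raise MaskIOError(f"mask file not found: {path}")
    suffixes = "".join(path.suffixes).lower()
    if suffixes.endswith((".nii", ".nii.gz")):
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
        if data.ndim != 3:
            raise MaskIOError(f"{path}: expected a 3D volume, got ndim={data.ndim}")
        zooms = img.header.get_zooms()[:3]
        if any(not np.isfinite(z) or z <= 0 for z in zooms):
            raise MaskIOError(f"{path}: missing or invalid spacing metadata {zooms}")
        origin = tuple(float(v) for v in img.affine[:3, 3])
        grid = VoxelGrid(tuple(data.shape), tuple(float(z) for z in zooms), origin, axis_roles)
    elif suffixes.endswith((".nrrd", ".nhdr")):
        import SimpleITK as sitk

        img = sitk.ReadImage(str(path))
        if img.GetDimension() != 3:
            raise MaskIOError(f"{path}: expected a 3D volume, got ndim={img.GetDimension()}")
        spacing = img.GetSpacing()
        if any(s <= 0 for s in spacing):
            raise MaskIOError(f"{path}: missing or invalid spacing metadata {spacing}")
        # GetArrayFromImage returns (z, y, x); transpose back to index order
        data = np.transpose(sitk.GetArrayFromImage(img), (2, 1, 0))
        grid = VoxelGrid(
            tuple(data.shape),
            tuple(float(s) for s in spacing),
            tuple(float(o) for o in img.GetOrigin()),
            axis_roles,
        )
    else:
        raise MaskIOError(f"unsupported mask format: {path}")
    return StructureMask(grid=grid, occupancy=data != 0, label=label)


def write_mask(mask: StructureMask, path: str | Path) -> Path:
    """Write a structure mask as uint8 NIfTI-1 (or NRRD by extension)."""
    path = Path(path)
    if not path.parent.exists():
        raise MaskIOError(f"parent directory does not exist: {path.parent}")
    data = mask.occupancy.astype(np.uint8)
    suffixes = "".join(path.suffixes).lower()
    if suffixes.endswith((".nii", ".nii.gz")):
        img = nib.Nifti1Image(data, _affine_from_grid(mask.grid))
        img.header.set_zooms(mask.grid.spacing)
        nib.save(img, str(path))
    elif suffixes.endswith((".nrrd", ".nhdr")):
        import SimpleITK as sitk

        img = sitk.GetImageFromArray(np.transpose(data, (2, 1, 0)))
        img.SetSpacing(mask.grid.spacing)
        img.SetOrigin(mask.grid.origin)
        sitk.WriteImage(img, str(path))
    else:
        raise MaskIOError(f"unsupported mask format: {path}")
    return path


def resample_to_grid(mask: StructureMask, target: VoxelGrid) -> StructureMask:
    """Nearest-neighbour resampling of a binary mask onto another grid.

    Each target voxel centre is mapped to the nearest source voxel; centres
    outside the source grid become background.  Used when two masks under
    comparison live on different grids (e.g. 3 mm CT slices vs 1 mm MR).
    """
    if mask.grid.same_geometry(target):
        return StructureMask(grid=target, occupancy=mask.occupancy.copy(), label=mask.label)
    idx = np.indices(target.shape, dtype=float)
    src = np.empty_like(idx)
    for ax in range(3):
        mm = target.origin[ax] + idx[ax] * target.spacing[ax]
        src[ax] = np.rint((mm - mask.grid.origin[ax]) / mask.grid.spacing[ax])
    inside = np.ones(target.shape, dtype=bool)
    for ax in range(3):
        inside &= (src[ax] >= 0) & (src[ax] <= mask.grid.shape[ax] - 1)
    occ = np.zeros(target.shape, dtype=bool)
    if inside.any():
        ii = tuple(src[ax][inside].astype(np.intp) for ax in range(3))
        occ[inside] = mask.occupancy[ii]
    return StructureMask(grid=target, occupancy=occ, label=mask.label)


@dataclasses.dataclass
class CohortManifest:
    """Tabular index binding mask files to (patient, scan, structure, role)."""

    records: pd.DataFrame

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.records, columns=MANIFEST_COLUMNS, copy=True)
        self.records = df.astype(str)

    def __len__(self) -> int:
        return len(self.records)

    def select(self, **where: str) -> pd.DataFrame:
        df = self.records
        for col, val in where.items():
            df = df[df[col] == val]
        return df

    def validate(self) -> list[str]:
        """Return invariant violations (empty list = valid), with row numbers."""
        df = self.records
        errors: list[str] = []
        bad_role = ~df["role"].isin(ROLES)
        for row in df.index[bad_role]:
            errors.append(f"row {row}: unknown role {df.loc[row, 'role']!r}")
        bad_scan = ~df["scan_id"].isin(SCAN_IDS)
        for row in df.index[bad_scan]:
            errors.append(f"row {row}: unknown scan_id {df.loc[row, 'scan_id']!r}")
        dup = df.duplicated(subset=["patient_id", "scan_id", "structure", "role"], keep=False)
        for row in df.index[dup & ~df.duplicated(subset=["patient_id", "scan_id", "structure", "role"])]:
            errors.append(
                f"row {row}: duplicate (patient, scan, structure, role) "
                f"{tuple(df.loc[row, ['patient_id', 'scan_id', 'structure', 'role']])}"
            )
        gt = set(
            map(
                tuple,
                df.loc[df["role"] == "ground_truth", ["patient_id", "scan_id", "structure"]].itertuples(index=False),
            )
        )
        needs_gt = df["role"] != "ground_truth"
        for row in df.index[needs_gt]:
            key = (df.loc[row, "patient_id"], df.loc[row, "scan_id"], df.loc[row, "structure"])
            if key not in gt:
                errors.append(f"row {row}: {df.loc[row, 'role']} record without ground truth for {key}")
        return sorted(errors)


def load_manifest(path: str | Path) -> CohortManifest:
    """Load and validate a cohort manifest CSV; raise on invariant violations."""
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ManifestError(f"{path}: missing manifest columns {missing}")
    manifest = CohortManifest(df[MANIFEST_COLUMNS])
    errors = manifest.validate()
    if errors:
        raise ManifestError(f"{path}: invalid manifest:\n" + "\n".join(errors))
    return manifest


def write_manifest(manifest: CohortManifest, path: str | Path) -> Path:
    path = Path(path)
    manifest.records.to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# Metric tables

METRIC_COLUMNS = [
    "patient_id",
    "scan_id",
    "structure",
    "arm",
    "dsc",
    "msd",
    "hd",
    "volume_test",
    "volume_ref",
    "status",
]
_METRIC_FLOATS = ["dsc", "msd", "hd", "volume_test", "volume_ref"]


def write_metric_table(records: pd.DataFrame | Iterable, path: str | Path) -> Path:
    """Write metric records as CSV, one row per record, full float precision."""
    df = pd.DataFrame(records)
    if not isinstance(records, pd.DataFrame):
        df = pd.DataFrame(list(records), columns=METRIC_COLUMNS)
    missing = [c for c in METRIC_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"metric table missing columns {missing}")
    df = df[METRIC_COLUMNS]
    df.to_csv(path, index=False, float_format="%.17g")  # exact float64 round trip
    return Path(path)


def read_metric_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        dtype={c: str for c in ["patient_id", "scan_id", "structure", "arm", "status"]},
        float_precision="round_trip",
    )
    missing = [c for c in METRIC_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: metric table missing columns {missing}")
    for col in _METRIC_FLOATS:
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError) as exc:
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()]
            raise ValueError(f"{path}: malformed numeric value in column {col!r}, rows {list(bad)}") from exc
    return df[METRIC_COLUMNS]
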