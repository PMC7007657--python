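"""Synthetic pelvic cohort generator.

Emulates the design of a 12-patient prostate radiotherapy propagation study
so the whole evaluation pipeline is testable without patient data.  Per
patient the generator produces:

* ground-truth delineations of 8 pelvic structures (prostate, seminal
  vesicles, elective nodal CTV56, rectum, bladder, both femoral heads,
  penile bulb) on a planning MR (pMR) and three follow-up MRs
  (MR10/20/30), with structure-specific inter-scan size and position
  variation (largest for bladder and rectum);
* a planning-CT surrogate (pCT) on a 3 mm-slice grid whose prostate is
  systematically larger than on MR (CT delineation margin);
* deformably propagated structures for two arms — CT→MR (4 targets) and
  MR→MR (3 targets) — with arm-specific residual error;
* an intra-observer re-delineation (IOV) of the pMR structures.

Propagation error model
-----------------------
Real deformable registration compensates most of the anatomical change
between planning and daily scan and leaves a residual error.  The
simulator mirrors this: the propagated structure is the zero level set of a
signed-distance blend ``(1−γ)·SDF(planning) + γ·SDF(daily)``, subsequently
warped by a smooth random residual displacement field whose per-component
standard deviation is the arm amplitude (CT→MR > MR→MR).  The compensation
γ is per arm (cross-modality registration compensates anatomy worse than
MR→MR) and decays with the planning-to-daily volume mismatch — the
registration copes with small differences but not large ones — so accuracy
degrades away from volume ratio 1.  Genus-1 ("pinhole") planning bladders —
a known propagation failure mode — receive γ = 0: the anatomical change is
not compensated at all.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import ndimage

from .io_formats import (
    CohortManifest,
    MANIFEST_COLUMNS,
    StructureMask,
    VoxelGrid,
    write_manifest,
    write_mask,
)

STRUCTURES = (
    "prostate",
    "SV",
    "CTV56",
    "rectum",
    "bladder",
    "femhead_L",
    "femhead_R",
    "penile_bulb",
)
MR_SCANS = ("pMR", "MR10", "MR20", "MR30")
CT_TARGETS = ("pMR", "MR10", "MR20", "MR30")
MR_TARGETS = ("MR10", "MR20", "MR30")


@dataclasses.dataclass(frozen=True)
class GridSpec:
    shape: tuple[int, int, int] = (128, 128, 160)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def to_grid(self) -> VoxelGrid:
        return VoxelGrid(self.shape, self.spacing)


@dataclasses.dataclass(frozen=True)
class OrganSpec:
    """Parametric shape of one structure plus its variability (all mm).

    ``scan_cov``/``patient_cov`` are coefficients of variation of a
    log-normal size factor applied to all size parameters; ``scan_jitter``/
    ``patient_jitter`` are per-axis standard deviations of centre shifts.
    Draws are clamped at 2.5 standard deviations so structures stay on the
    grid.
    """

    family: str  # ellipsoid | sphere | tube | paired_ellipsoid
    center: tuple[float, float, float]
    size: tuple[float, ...]  # family-specific, see _rasterize
    scan_cov: float = 0.03
    scan_jitter: float = 1.0
    patient_cov: float = 0.08
    patient_jitter: float = 2.0


@dataclasses.dataclass(frozen=True)
class DeformationSpec:
    """Smooth random residual displacement: per-component SD (mm) and
    Gaussian correlation length (mm)."""

    amplitude_mm: float
    correlation_mm: float = 20.0

    def __post_init__(self) -> None:
        if self.amplitude_mm < 0:
            raise ValueError("amplitude must be >= 0")
        if self.correlation_mm <= 0:
            raise ValueError("correlation length must be > 0")


def default_organ_specs() -> dict[str, OrganSpec]:
    """Pelvic layout on the default 128×128×160 mm field of view.

    Sizes give planning-MR volumes near published medians (prostate ≈ 38,
    bladder ≈ 180, rectum ≈ 90 cm³); bladder and rectum get the largest
    inter-scan variation, femoral heads are nearly rigid.
    """
    return {
        "prostate": OrganSpec("ellipsoid", (64, 74, 62), (23, 20, 20), 0.03, 1.0, 0.12, 2.5),
        "SV": OrganSpec("paired_ellipsoid", (64, 86, 78), (14, 8, 11, 9), 0.05, 1.5, 0.12, 2.5),
        "CTV56": OrganSpec("paired_ellipsoid", (64, 64, 95), (26, 10, 16, 40), 0.02, 1.0, 0.04, 2.0),
        "rectum": OrganSpec("tube", (64, 90, 82), (15, 4, 52), 0.10, 2.0, 0.08, 2.0),
        "bladder": OrganSpec("sphere", (64, 63, 91), (34,), 0.06, 2.0, 0.10, 2.5),
        "femhead_L": OrganSpec("sphere", (100, 64, 80), (20,), 0.01, 0.5, 0.04, 1.5),
        "femhead_R": OrganSpec("sphere", (28, 64, 80), (20,), 0.01, 0.5, 0.04, 1.5),
        "penile_bulb": OrganSpec("ellipsoid", (64, 78, 30), (11, 9, 8), 0.05, 1.0, 0.10, 2.0),
    }


@dataclasses.dataclass
class CohortConfig:
    """Study-design parameters of the synthetic cohort.

    Defaults reproduce the evaluated design: 12 patients, 5 scans, 8
    structures, 4 CT→MR + 3 MR→MR propagations per structure (672
    propagated structures in total) plus one intra-observer re-delineation
    per structure on pMR.
    """

    n_patients: int = 12
    structures: tuple[str, ...] = STRUCTURES
    arm_amplitudes: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: {"CT_MR": 2.0, "MR_MR": 1.0, "IOV": 0.8}
    )
    correlation_mm: float = 20.0
    iov_correlation_mm: float = 12.0
    # fraction of the planning-to-daily anatomical change the registration
    # recovers; cross-modality (CT->MR) registration compensates worse
    dir_compensation: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: {"CT_MR": 0.70, "MR_MR": 0.90}
    )
    dir_capacity_lnratio: float = 0.55  # volume-mismatch scale at which compensation collapses
    ct_margin_mm: Mapping[str, float] = dataclasses.field(default_factory=lambda: {"prostate": 2.0})
    ct_slice_mm: float | None = 3.0  # pCT surrogate slice thickness; None = MR grid
    # pCT is acquired in the same session as pMR: its anatomy is the pMR
    # state plus this fraction of the usual scan-to-scan variability
    ct_session_fraction: float = 0.5
    grid: GridSpec = dataclasses.field(default_factory=GridSpec)
    n_pinhole_patients: int = 3
    pinhole_radius_mm: float = 6.0
    master_seed: int = 0
    organ_specs: Mapping[str, OrganSpec] = dataclasses.field(default_factory=default_organ_specs)

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if isinstance(self.dir_compensation, (int, float)):
            self.dir_compensation = {
                "CT_MR": float(self.dir_compensation),
                "MR_MR": float(self.dir_compensation),
            }
        for arm in ("CT_MR", "MR_MR"):
            g = self.dir_compensation.get(arm)
            if g is None or not (0.0 <= g <= 1.0):
                raise ValueError(f"dir_compensation[{arm}] must be in [0, 1]")
        if self.n_pinhole_patients > self.n_patients:
            raise ValueError("n_pinhole_patients cannot exceed n_patients")
        missing = [s for s in self.structures if s not in self.organ_specs]
        if missing:
            raise ValueError(f"no organ spec for structures {missing}")
        for arm in ("CT_MR", "MR_MR", "IOV"):
            if self.arm_amplitudes.get(arm, -1) < 0:
                raise ValueError(f"arm amplitude for {arm} must be >= 0")

    @classmethod
    def reduced(cls, master_seed: int = 0, **overrides) -> "CohortConfig":
        """Reduced-resolution preset (same 128×128×160 mm field of view on a
        64³ grid) for fast test runs."""
        overrides.setdefault("grid", GridSpec((64, 64, 64), (2.0, 2.0, 2.5)))
        return cls(master_seed=master_seed, **overrides)

    def to_jsonable(self) -> dict:
        d = dataclasses.asdict(self)
        d["arm_amplitudes"] = dict(self.arm_amplitudes)
        d["ct_margin_mm"] = dict(self.ct_margin_mm)
        d["organ_specs"] = {k: dataclasses.asdict(v) for k, v in self.organ_specs.items()}
        return d


# ---------------------------------------------------------------------------
# Rasterization


def _coords(grid: VoxelGrid) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    return tuple(
        (grid.origin[ax] + np.arange(grid.shape[ax]) * grid.spacing[ax]).reshape(
            [-1 if a == ax else 1 for a in range(3)]
        )
        for ax in range(3)
    )


def _rasterize(
    spec: OrganSpec,
    grid: VoxelGrid,
    center: np.ndarray,
    size: np.ndarray,
    margin: float = 0.0,
    pinhole_radius: float = 0.0,
) -> np.ndarray:
    """Voxelize one organ shape family; ``margin`` expands all size
    parameters (an analytic dilation of the ideal shape)."""
    X, Y, Z = _coords(grid)
    cx, cy, cz = center
    if spec.family == "sphere":
        (r,) = size
        r = r + margin
        occ = (X - cx) ** 2 + (Y - cy) ** 2 + (Z - cz) ** 2 <= r**2
        if pinhole_radius > 0:
            # tunnel along AP through the structure centre -> genus 1
            occ &= (X - cx) ** 2 + (Z - cz) ** 2 > pinhole_radius**2
    elif spec.family == "ellipsoid":
        a, b, c = (s + margin for s in size)
        occ = ((X - cx) / a) ** 2 + ((Y - cy) / b) ** 2 + ((Z - cz) / c) ** 2 <= 1.0
    elif spec.family == "paired_ellipsoid":
        dx, a, b, c = size
        a, b, c = a + margin, b + margin, c + margin
        occ = ((X - (cx - dx)) / a) ** 2 + ((Y - cy) / b) ** 2 + ((Z - cz) / c) ** 2 <= 1.0
        occ |= ((X - (cx + dx)) / a) ** 2 + ((Y - cy) / b) ** 2 + ((Z - cz) / c) ** 2 <= 1.0
    elif spec.family == "tube":
        radius, bow, half_len = size
        radius = radius + margin
        z0, z1 = cz - half_len, cz + half_len
        axis_y = cy + bow * np.sin(np.pi * (Z - z0) / max(z1 - z0, 1e-9))
        occ = ((X - cx) ** 2 + (Y - axis_y) ** 2 <= radius**2) & (Z >= z0) & (Z <= z1)
    else:
        raise ValueError(f"unknown shape family {spec.family!r}")
    return occ


def _max_extent(spec: OrganSpec, size: np.ndarray, margin: float) -> np.ndarray:
    """Conservative per-axis half-extent (mm) of the shape around its centre."""
    if spec.family == "sphere":
        r = size[0] + margin
        return np.array([r, r, r])
    if spec.family == "ellipsoid":
        return np.asarray(size) + margin
    if spec.family == "paired_ellipsoid":
        dx, a, b, c = size
        return np.array([dx + a + margin, b + margin, c + margin])
    if spec.family == "tube":
        radius, bow, half_len = size
        return np.array([radius + margin, radius + bow + margin, half_len])
    raise ValueError(spec.family)


def _check_fits(label: str, spec: OrganSpec, grid: VoxelGrid, center: np.ndarray, size: np.ndarray, margin: float) -> None:
    ext = _max_extent(spec, size, margin)
    lo = center - ext
    hi = center + ext
    gmin = np.asarray(grid.origin)
    gmax = gmin + np.asarray(grid.extent_mm())
    if np.any(lo < gmin - 1e-6) or np.any(hi > gmax + 1e-6):
        raise ValueError(f"structure {label!r} exceeds the grid: extent [{lo}, {hi}] vs grid [{gmin}, {gmax}]")


def make_organ_phantom(
    specs: Mapping[str, OrganSpec],
    grid: VoxelGrid,
    rng: np.random.Generator | None = None,
    size_factors: Mapping[str, float] | None = None,
    center_shifts: Mapping[str, np.ndarray] | None = None,
    margins: Mapping[str, float] | None = None,
    pinhole: bool = False,
    pinhole_radius: float = 6.0,
    scan_params: Mapping[str, tuple[float, np.ndarray]] | None = None,
) -> dict[str, StructureMask]:
    """Rasterize one scan's ground-truth structure set.

    Scan-to-scan variability is drawn from ``rng`` per structure (clamped
    log-normal size factor, clamped Gaussian centre shift) unless explicit
    ``scan_params`` are passed (used to rasterize one anatomical state on
    two grids); ``size_factors``/``center_shifts`` multiply/add on top
    (used for the patient level).  ``pinhole`` tunnels the bladder
    (genus 1).
    """
    rng = rng or np.random.default_rng(0)
    if scan_params is None:
        scan_params = draw_scan_params(specs, rng)
    masks: dict[str, StructureMask] = {}
    for label, spec in specs.items():
        f_scan, shift_scan = scan_params[label]
        f = f_scan * (size_factors or {}).get(label, 1.0)
        # bound the combined (patient x scan) factor so structures always fit
        sig_tot = np.sqrt(np.log1p(spec.scan_cov**2) + np.log1p(spec.patient_cov**2))
        f = float(np.clip(f, np.exp(-2.5 * sig_tot), np.exp(2.5 * sig_tot)))
        center = np.asarray(spec.center, dtype=float) + shift_scan + np.asarray(
            (center_shifts or {}).get(label, np.zeros(3)), dtype=float
        )
        size = np.asarray(spec.size, dtype=float).copy()
        if spec.family == "paired_ellipsoid":
            size[1:] *= f  # lateral separation fixed, lobes scale
        elif spec.family == "tube":
            size[:2] *= f  # radius and bow scale, length is fixed
        else:
            size *= f
        margin = (margins or {}).get(label, 0.0)
        _check_fits(label, spec, grid, center, size, margin)
        occ = _rasterize(
            spec,
            grid,
            center,
            size,
            margin=margin,
            pinhole_radius=pinhole_radius if (pinhole and label == "bladder") else 0.0,
        )
        masks[label] = StructureMask(grid=grid, occupancy=occ, label=label)
    return masks


def draw_scan_params(
    specs: Mapping[str, OrganSpec], rng: np.random.Generator
) -> dict[str, tuple[float, np.ndarray]]:
    """One scan's anatomical state: per-structure (size factor, centre shift)."""
    return {
        label: (_lognormal_factor(rng, spec.scan_cov), _clamped_normal(rng, spec.scan_jitter, 3))
        for label, spec in specs.items()
    }


def _lognormal_factor(rng: np.random.Generator, cov: float, clamp_sd: float = 2.5) -> float:
    if cov <= 0:
        return 1.0
    z = float(np.clip(rng.standard_normal(), -clamp_sd, clamp_sd))
    return float(np.exp(z * np.sqrt(np.log1p(cov**2)) - 0.5 * np.log1p(cov**2)))


def _clamped_normal(rng: np.random.Generator, sd: float, n: int, clamp_sd: float = 2.5) -> np.ndarray:
    if sd <= 0:
        return np.zeros(n)
    return np.clip(rng.standard_normal(n), -clamp_sd, clamp_sd) * sd


# ---------------------------------------------------------------------------
# Deformation model


def random_displacement_field(
    spec: DeformationSpec,
    grid: VoxelGrid,
    rng: np.random.Generator,
) -> np.ndarray:
    """Smooth random vector field, shape (3, *grid.shape), in mm.

    White Gaussian noise on a coarse lattice (one node per third of the
    correlation length) is smoothed with a Gaussian kernel of the
    correlation length, linearly interpolated onto the voxel grid, and
    renormalised so each component's empirical standard deviation equals
    the amplitude exactly.  The coarse lattice is purely an efficiency
    device: the field has no energy below the correlation length anyway.
    Deterministic for a fixed generator state; amplitude 0 yields the zero
    field.
    """
    field = np.zeros((3,) + grid.shape)
    if spec.amplitude_mm == 0:
        return field
    h = spec.correlation_mm / 3.0  # lattice pitch, mm
    extent = grid.extent_mm()
    lat_shape = tuple(int(np.ceil(e / h)) + 7 for e in extent)
    # voxel centres in lattice coordinates (offset by the 3-node pad)
    coords = np.indices(grid.shape, dtype=float)
    for ax in range(3):
        coords[ax] = coords[ax] * grid.spacing[ax] / h + 3.0
    for c in range(3):
        noise = rng.standard_normal(lat_shape)
        noise = ndimage.gaussian_filter(noise, sigma=3.0, mode="reflect")  # sigma = correlation in lattice units
        comp = ndimage.map_coordinates(noise, coords, order=1, mode="nearest")
        sd = comp.std()
        if sd == 0:
            continue
        field[c] = (comp - comp.mean()) * (spec.amplitude_mm / sd)
    return field


def warp_mask(mask: StructureMask, field: np.ndarray, out_grid: VoxelGrid | None = None) -> StructureMask:
    """Displace a binary mask by a vector field (mm), backward mapping with
    nearest-neighbour sampling: out(x) = in(x − d(x)).

    A zero field is the identity; a constant whole-voxel translation shifts
    the mask exactly.  ``out_grid`` may differ from the mask grid (the field
    lives on the output grid), which doubles as nearest-neighbour
    resampling.
    """
    out_grid = out_grid or mask.grid
    if field.shape != (3,) + out_grid.shape:
        raise ValueError(f"field shape {field.shape} does not match grid {out_grid.shape}")
    idx = np.indices(out_grid.shape, dtype=float)
    src = np.empty_like(idx)
    for ax in range(3):
        mm = out_grid.origin[ax] + idx[ax] * out_grid.spacing[ax] - field[ax]
        src[ax] = (mm - mask.grid.origin[ax]) / mask.grid.spacing[ax]
    occ = ndimage.map_coordinates(mask.occupancy.astype(np.uint8), src, order=0, mode="constant", cval=0)
    return StructureMask(grid=out_grid, occupancy=occ.astype(bool), label=mask.label)


def perturb_contour(
    mask: StructureMask,
    sigma_mm: float,
    rng: np.random.Generator | int,
    correlation_mm: float = 12.0,
) -> StructureMask:
    """Intra-observer re-delineation surrogate: displace the contour by a
    smooth low-amplitude field of per-component SD ``sigma_mm``.  The
    expected surface distance to the original grows monotonically with
    sigma."""
    if sigma_mm < 0:
        raise ValueError("sigma must be >= 0")
    if sigma_mm == 0:
        return StructureMask(grid=mask.grid, occupancy=mask.occupancy.copy(), label=mask.label)
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    field = random_displacement_field(DeformationSpec(sigma_mm, correlation_mm), mask.grid, rng)
    return warp_mask(mask, field)


# ---------------------------------------------------------------------------
# Propagation (residual-error DIR surrogate)


def _signed_distance(occ: np.ndarray, spacing: tuple[float, float, float]) -> np.ndarray:
    """Signed Euclidean distance (mm), negative inside the structure."""
    if not occ.any():
        return np.full(occ.shape, np.inf)
    outside = ndimage.distance_transform_edt(~occ, sampling=spacing)
    inside = ndimage.distance_transform_edt(occ, sampling=spacing)
    return outside - inside


def propagate_structure(
    planning_sdf: np.ndarray,
    daily_sdf: np.ndarray,
    gamma: float,
    field: np.ndarray,
    grid: VoxelGrid,
    label: str,
) -> StructureMask:
    """DIR propagation surrogate: blend planning and daily signed-distance
    functions by the compensation factor and warp by the residual field."""
    if gamma <= 0:
        blend = planning_sdf
    elif gamma >= 1:
        blend = daily_sdf
    else:
        blend = (1.0 - gamma) * planning_sdf + gamma * daily_sdf
    base = StructureMask(grid=grid, occupancy=blend < 0, label=label)
    return warp_mask(base, field)


def _union_crop(occs: list[np.ndarray], pad_vox: np.ndarray, shape: tuple[int, int, int]) -> tuple[slice, slice, slice]:
    """Padded bounding slices covering every occupied voxel of all masks."""
    lo = np.array(shape)
    hi = np.zeros(3, dtype=int)
    for occ in occs:
        idx = np.argwhere(occ)
        lo = np.minimum(lo, idx.min(axis=0))
        hi = np.maximum(hi, idx.max(axis=0) + 1)
    lo = np.maximum(lo - pad_vox, 0)
    hi = np.minimum(hi + pad_vox, shape)
    return tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))


def _warp_occ(occ: np.ndarray, field_crop: np.ndarray, spacing: tuple[float, float, float]) -> np.ndarray:
    """Backward nearest-neighbour warp of a (cropped) occupancy array."""
    idx = np.indices(occ.shape, dtype=float)
    for ax in range(3):
        idx[ax] -= field_crop[ax] / spacing[ax]
    return ndimage.map_coordinates(occ.astype(np.uint8), idx, order=0, mode="constant", cval=0).astype(bool)


# ---------------------------------------------------------------------------
# Cohort simulation


@dataclasses.dataclass
class SyntheticCohort:
    """In-memory cohort: masks keyed by (patient, scan, structure, role)."""

    config: CohortConfig
    manifest: CohortManifest
    masks: dict[tuple[str, str, str, str], StructureMask] | None = None

    def mask(self, patient_id: str, scan_id: str, structure: str, role: str) -> StructureMask:
        if self.masks is None:
            raise ValueError("cohort was written to disk; load masks via the manifest paths")
        return self.masks[(patient_id, scan_id, structure, role)]


def _ct_grid(config: CohortConfig) -> VoxelGrid:
    mr = config.grid.to_grid()
    if config.ct_slice_mm is None:
        return mr
    cc = mr.axis_of("CC")
    spacing = list(mr.spacing)
    shape = list(mr.shape)
    extent = shape[cc] * spacing[cc]
    spacing[cc] = float(config.ct_slice_mm)
    shape[cc] = max(1, int(np.ceil(extent / config.ct_slice_mm)))
    return VoxelGrid(tuple(shape), tuple(spacing), mr.origin, mr.axis_roles)


def simulate_cohort(config: CohortConfig, out_dir: str | Path | None = None) -> SyntheticCohort:
    """Generate the full synthetic cohort.

    With ``out_dir`` the masks are written as NIfTI (.nii.gz) plus a
    manifest CSV and a JSON config echo, and only the manifest is retained
    in memory; without it all masks stay in memory with empty paths.
    Fully deterministic under ``config.master_seed`` via hierarchical
    per-patient seed spawning.
    """
    grid = config.grid.to_grid()
    ct_grid = _ct_grid(config)
    specs = {s: config.organ_specs[s] for s in config.structures}
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "masks").mkdir(exist_ok=True)

    masks: dict[tuple[str, str, str, str], StructureMask] = {}
    rows: list[dict] = []

    def emit(patient: str, scan: str, structure: str, role: str, mask: StructureMask) -> None:
        path = ""
        if out_dir is not None:
            path = f"masks/{patient}_{scan}_{structure}_{role}.nii.gz"
            write_mask(mask, out_dir / path)
        else:
            masks[(patient, scan, structure, role)] = mask
        rows.append(
            {"patient_id": patient, "scan_id": scan, "structure": structure, "role": role, "path": path}
        )

    root_ss = np.random.SeedSequence(config.master_seed)
    patient_seeds = root_ss.spawn(config.n_patients)
    for p in range(config.n_patients):
        patient = f"P{p + 1:02d}"
        prng = np.random.default_rng(patient_seeds[p])
        pinhole = p < config.n_pinhole_patients
        size_factors = {s: _lognormal_factor(prng, specs[s].patient_cov) for s in specs}
        center_shifts = {s: _clamped_normal(prng, specs[s].patient_jitter, 3) for s in specs}

        # ground truths on the four MR scans (pMR first = planning anatomy)
        gt: dict[str, dict[str, StructureMask]] = {}
        scan_params: dict[str, dict] = {}
        for scan in MR_SCANS:
            scan_params[scan] = draw_scan_params(specs, prng)
            gt[scan] = make_organ_phantom(
                specs,
                grid,
                size_factors=size_factors,
                center_shifts=center_shifts,
                pinhole=pinhole and scan == "pMR",
                pinhole_radius=config.pinhole_radius_mm,
                scan_params=scan_params[scan],
            )
            for s, m in gt[scan].items():
                emit(patient, scan, s, "ground_truth", m)

        # planning-CT surrogate: acquired in the same session as pMR, so
        # its anatomy is the pMR state plus a small intra-session
        # perturbation, with the CT delineation margin on top; rasterized
        # analytically both on the MR grid (propagation source) and the
        # coarser CT grid (emitted file)
        frac = config.ct_session_fraction
        ct_params = {}
        for s, spec in specs.items():
            f0, sh0 = scan_params["pMR"][s]
            ct_params[s] = (
                f0 * _lognormal_factor(prng, frac * spec.scan_cov),
                sh0 + _clamped_normal(prng, frac * spec.scan_jitter, 3),
            )
        ct_kwargs = dict(
            size_factors=size_factors,
            center_shifts=center_shifts,
            margins=config.ct_margin_mm,
            pinhole=pinhole,
            pinhole_radius=config.pinhole_radius_mm,
            scan_params=ct_params,
        )
        ct_src = make_organ_phantom(specs, grid, **ct_kwargs)
        for s, m in make_organ_phantom(specs, ct_grid, **ct_kwargs).items():
            emit(patient, "pCT", s, "ground_truth", m)

        # All per-structure work (signed distances, blending, warping) runs
        # on a padded per-structure crop of the grid: structures are local,
        # so this is exact and much cheaper than full-grid transforms.
        max_amp = max(config.arm_amplitudes.values())
        pad_mm = 4.0 * max_amp + 6.0
        spacing = np.asarray(grid.spacing)
        pad_vox = np.ceil(pad_mm / spacing).astype(int)
        crops = {
            s: _union_crop(
                [gt[scan][s].occupancy for scan in MR_SCANS] + [ct_src[s].occupancy], pad_vox, grid.shape
            )
            for s in specs
        }

        pmr_sdf = {s: _signed_distance(gt["pMR"][s].occupancy[crops[s]], grid.spacing) for s in specs}
        ct_source_sdf = {s: _signed_distance(ct_src[s].occupancy[crops[s]], grid.spacing) for s in specs}

        daily_sdf_cache: dict[tuple[str, str], np.ndarray] = {}

        def daily_sdf(scan: str, s: str) -> np.ndarray:
            key = (scan, s)
            if key not in daily_sdf_cache:
                daily_sdf_cache[key] = (
                    pmr_sdf[s] if scan == "pMR" else _signed_distance(gt[scan][s].occupancy[crops[s]], grid.spacing)
                )
            return daily_sdf_cache[key]

        def propagate(planning_sdf: np.ndarray, scan: str, s: str, g: float, field: np.ndarray) -> StructureMask:
            # registration copes with small anatomical differences but not
            # large ones: compensation decays with the planning/daily
            # volume mismatch (log-ratio, Gaussian capacity)
            if g > 0 and config.dir_capacity_lnratio > 0:
                v_p = max(int(np.count_nonzero(planning_sdf < 0)), 1)
                v_d = max(int(np.count_nonzero(daily_sdf(scan, s) < 0)), 1)
                d = abs(np.log(v_p / v_d))
                g = g * float(np.exp(-((d / config.dir_capacity_lnratio) ** 2)))
            blend = planning_sdf if g <= 0 else (1.0 - g) * planning_sdf + g * daily_sdf(scan, s)
            crop = crops[s]
            occ_crop = _warp_occ(blend < 0, field[(slice(None),) + crop], grid.spacing)
            occ = np.zeros(grid.shape, dtype=bool)
            occ[crop] = occ_crop
            return StructureMask(grid=grid, occupancy=occ, label=s)

        # CT->MR propagations (4 targets)
        for scan in CT_TARGETS:
            field = random_displacement_field(
                DeformationSpec(config.arm_amplitudes["CT_MR"], config.correlation_mm), grid, prng
            )
            for s in specs:
                g = 0.0 if (pinhole and s == "bladder") else config.dir_compensation["CT_MR"]
                emit(patient, scan, s, "propagated_CT_MR", propagate(ct_source_sdf[s], scan, s, g, field))

        # MR->MR propagations (3 targets)
        for scan in MR_TARGETS:
            field = random_displacement_field(
                DeformationSpec(config.arm_amplitudes["MR_MR"], config.correlation_mm), grid, prng
            )
            for s in specs:
                g = 0.0 if (pinhole and s == "bladder") else config.dir_compensation["MR_MR"]
                emit(patient, scan, s, "propagated_MR_MR", propagate(pmr_sdf[s], scan, s, g, field))

        # intra-observer re-delineation on pMR (one field per patient)
        iov_field = random_displacement_field(
            DeformationSpec(config.arm_amplitudes["IOV"], config.iov_correlation_mm), grid, prng
        )
        for s in specs:
            crop = crops[s]
            occ = np.zeros(grid.shape, dtype=bool)
            occ[crop] = _warp_occ(gt["pMR"][s].occupancy[crop], iov_field[(slice(None),) + crop], grid.spacing)
            emit(patient, "pMR", s, "redelineation_IOV", StructureMask(grid=grid, occupancy=occ, label=s))

    manifest = CohortManifest(pd.DataFrame(rows, columns=MANIFEST_COLUMNS))
    errors = manifest.validate()
    if errors:  # defensive: by construction this cannot happen
        raise RuntimeError("generated manifest is invalid:\n" + "\n".join(errors))
    if out_dir is not None:
        write_manifest(manifest, out_dir / "manifest.csv")
        (out_dir / "cohort_config.json").write_text(json.dumps(config.to_jsonable(), indent=2, default=str))
        return SyntheticCohort(config=config, manifest=manifest, masks=None)
    return SyntheticCohort(config=config, manifest=manifest, masks=masks)


# ---------------------------------------------------------------------------
# Tiny deterministic fixtures used by the test-suite (`fixtures` mode)


def sphere_mask(
    radius_mm: float,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    pad_mm: float = 3.0,
    label: str = "other",
) -> StructureMask:
    """Voxelized sphere centred on its own tight grid."""
    shape = tuple(int(np.ceil(2 * (radius_mm + pad_mm) / s)) + 1 for s in spacing)
    grid = VoxelGrid(shape, spacing)
    center = np.array([(n - 1) * s / 2 for n, s in zip(shape, spacing)])
    X, Y, Z = _coords(grid)
    occ = (X - center[0]) ** 2 + (Y - center[1]) ** 2 + (Z - center[2]) ** 2 <= radius_mm**2
    return StructureMask(grid=grid, occupancy=occ, label=label)


def torus_mask(
    major_mm: float = 10.0,
    minor_mm: float = 4.0,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    label: str = "other",
) -> StructureMask:
    """Voxelized solid torus (genus 1) around the CC axis."""
    half = major_mm + minor_mm + 3.0
    shape = tuple(int(np.ceil(2 * half / s)) + 1 for s in spacing)
    grid = VoxelGrid(shape, spacing)
    center = np.array([(n - 1) * s / 2 for n, s in zip(shape, spacing)])
    X, Y, Z = _coords(grid)
    rho = np.sqrt((X - center[0]) ** 2 + (Y - center[1]) ** 2)
    occ = (rho - major_mm) ** 2 + (Z - center[2]) ** 2 <= minor_mm**2
    return StructureMask(grid=grid, occupancy=occ, label=label)
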