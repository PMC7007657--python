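"""End-to-end analysis: cohort -> metrics -> statistics -> projection maps.

``run_pipeline`` drives the whole evaluation from a single configuration:
simulate (or load) a cohort, compute one metric record per propagated /
re-delineated structure against the ground truth of the same scan, build
the median tables with Wilcoxon tests, the volume-ratio table, and the
population percentile projection maps.  Individual structure failures are
recorded with a status and never abort the run.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

from . import __version__
from .cohort_stats import (
    ARM_PAIRS,
    METRICS,
    comparison_table,
    paired_comparison,
    patient_scan_average,
    planning_volume_comparison,
    population_median_table,
    volume_ratio_table,
)
from .geometry_metrics import compare_structures, surface_distances, volume
from .io_formats import (
    CohortManifest,
    StructureMask,
    load_manifest,
    read_mask,
    resample_to_grid,
    write_metric_table,
)
from .projection_maps import (
    PLANES,
    aggregate_population_map,
    bounding_box,
    mean_structure_aspect,
    project_deviations,
    render_map,
    write_map_csv,
)
from .synthetic_cohort import CohortConfig, SyntheticCohort, simulate_cohort

logger = logging.getLogger("dirqa")

ROLE_TO_ARM = {
    "propagated_CT_MR": "CT_MR",
    "propagated_MR_MR": "MR_MR",
    "redelineation_IOV": "IOV",
}


@dataclasses.dataclass
class RunConfig:
    """Pipeline options; every default is logged when used."""

    cohort: CohortConfig | None = None  # simulate when set ...
    manifest_path: str | None = None  # ... else load this manifest
    base_dir: str | None = None  # directory mask paths are relative to
    out_dir: str = "dirqa_out"
    seed: int | None = None  # overrides cohort.master_seed
    msd_mode: str = "symmetric"
    hd_percentile: float = 100.0
    pixel_shape: tuple[int, int] = (64, 64)
    percentiles: tuple[float, ...] = (50.0, 90.0)
    min_scans_per_pixel: int = 1
    stats_mode: str = "exact"
    write_masks: bool = False
    render_png: bool = True

    def resolved_cohort(self) -> CohortConfig | None:
        if self.cohort is None:
            return None
        if self.seed is None:
            return self.cohort
        return dataclasses.replace(self.cohort, master_seed=int(self.seed))


def _loader_for(cohort: SyntheticCohort | None, manifest: CohortManifest, base_dir: Path | None) -> Callable:
    def load(patient: str, scan: str, structure: str, role: str, path: str) -> StructureMask:
        if cohort is not None and cohort.masks is not None:
            return cohort.mask(patient, scan, structure, role)
        full = Path(path)
        if base_dir is not None and not full.is_absolute():
            full = base_dir / full
        return read_mask(full, label=structure)

    return load


def evaluate_cohort(
    manifest: CohortManifest,
    loader: Callable,
    msd_mode: str = "symmetric",
    hd_percentile: float = 100.0,
    pixel_shape: tuple[int, int] = (64, 64),
    collect_projections: bool = True,
) -> dict:
    """Compute metric records, ground-truth volumes and per-scan projection
    grids for every non-ground-truth manifest record.

    Masks on a grid different from their ground truth are resampled onto the
    finer grid (smaller voxel volume) with nearest neighbours; each such
    event is logged.  Returns a dict with keys ``records`` (DataFrame),
    ``gt_volumes`` (DataFrame), ``projections`` (nested dict), ``boxes``
    and bookkeeping counts.
    """
    df = manifest.records
    gt_masks_index = df[df["role"] == "ground_truth"]
    gt_rows = {
        (r.patient_id, r.scan_id, r.structure): r.path for r in gt_masks_index.itertuples(index=False)
    }
    gt_volumes = []
    for (patient, scan, structure), path in sorted(gt_rows.items()):
        m = loader(patient, scan, structure, "ground_truth", path)
        gt_volumes.append(
            {"patient_id": patient, "scan_id": scan, "structure": structure, "volume": volume(m)}
        )
    gt_volumes = pd.DataFrame(gt_volumes)

    records = []
    projections: dict = {}
    boxes: dict = {}
    n_resampled = 0
    eval_rows = df[df["role"] != "ground_truth"]
    for row in eval_rows.itertuples(index=False):
        arm = ROLE_TO_ARM[row.role]
        test = loader(row.patient_id, row.scan_id, row.structure, row.role, row.path)
        ref = loader(
            row.patient_id, row.scan_id, row.structure, "ground_truth", gt_rows[(row.patient_id, row.scan_id, row.structure)]
        )
        if not test.grid.same_geometry(ref.grid):
            if test.grid.voxel_volume_mm3 <= ref.grid.voxel_volume_mm3:
                ref = resample_to_grid(ref, test.grid)
            else:
                test = resample_to_grid(test, ref.grid)
            n_resampled += 1
            logger.info(
                "resampled %s/%s/%s onto the finer grid (nearest neighbour)",
                row.patient_id,
                row.scan_id,
                row.structure,
            )
        labels = {
            "patient_id": row.patient_id,
            "scan_id": row.scan_id,
            "structure": row.structure,
            "arm": arm,
        }
        rec, sds = compare_structures(
            test, ref, labels=labels, msd_mode=msd_mode, hd_percentile=hd_percentile, return_distances=True
        )
        records.append(dataclasses.asdict(rec))
        if collect_projections and rec.status == "ok":
            box = bounding_box(test)
            grids = project_deviations(sds, box, pixel_shape, labels=labels)
            key = (row.structure, arm)
            projections.setdefault(key, []).append(grids)
            boxes.setdefault(key, []).append(box)

    records = pd.DataFrame(
        records,
        columns=["patient_id", "scan_id", "structure", "arm", "dsc", "msd", "hd", "volume_test", "volume_ref", "status"],
    )
    return {
        "records": records,
        "gt_volumes": gt_volumes,
        "projections": projections,
        "boxes": boxes,
        "n_resampled": n_resampled,
        "n_failed": int((records["status"] != "ok").sum()),
    }


def run_pipeline(config: RunConfig) -> Path:
    """Run the full analysis; returns the output directory.

    Outputs: ``metrics.csv``, ``gt_volumes.csv``, ``table1_{dsc,msd,hd}.csv``,
    ``table2_volumes.csv``, ``volume_ratio.csv``, per-structure/arm
    percentile projection maps (CSV matrix + optional PNG) under ``maps/``,
    and ``run.json`` with the config echo, version, seed and record counts.
    Idempotent (byte-identical CSVs) for a fixed config and seed.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "maps").mkdir(exist_ok=True)

    cohort: SyntheticCohort | None = None
    if config.cohort is not None:
        cohort_cfg = config.resolved_cohort()
        cohort = simulate_cohort(cohort_cfg, out_dir=(out / "cohort") if config.write_masks else None)
        manifest = cohort.manifest
        base_dir = out / "cohort" if config.write_masks else None
        seed_used = cohort_cfg.master_seed
    elif config.manifest_path is not None:
        manifest = load_manifest(config.manifest_path)
        base_dir = Path(config.base_dir) if config.base_dir else Path(config.manifest_path).parent
        seed_used = config.seed
    else:
        raise ValueError("RunConfig needs either a cohort simulation config or a manifest path")

    loader = _loader_for(cohort, manifest, base_dir)
    logger.info(
        "evaluation settings: msd_mode=%s hd_percentile=%s pixel_shape=%s percentiles=%s stats_mode=%s",
        config.msd_mode,
        config.hd_percentile,
        config.pixel_shape,
        config.percentiles,
        config.stats_mode,
    )
    ev = evaluate_cohort(
        manifest,
        loader,
        msd_mode=config.msd_mode,
        hd_percentile=config.hd_percentile,
        pixel_shape=config.pixel_shape,
    )
    records: pd.DataFrame = ev["records"]
    write_metric_table(records, out / "metrics.csv")
    ev["gt_volumes"].to_csv(out / "gt_volumes.csv", index=False)

    # statistics
    summaries = patient_scan_average(records)
    summaries.to_csv(out / "patient_summaries.csv", index=False)
    med = population_median_table(summaries)
    med.to_csv(out / "population_medians.csv")
    all_results = []
    for arm_a, arm_b in ARM_PAIRS:
        all_results.extend(paired_comparison(summaries, arm_a, arm_b, mode=config.stats_mode))
    for metric in METRICS:
        comparison_table(all_results, metric).to_csv(out / f"table1_{metric}.csv", index=False)
    planning_volume_comparison(ev["gt_volumes"], mode=config.stats_mode).to_csv(
        out / "table2_volumes.csv", index=False
    )
    vr = volume_ratio_table(records, ev["gt_volumes"])
    vr.to_csv(out / "volume_ratio.csv", index=False)

    # population projection maps
    n_maps = 0
    for (structure, arm), grid_sets in sorted(ev["projections"].items()):
        aspects = mean_structure_aspect(ev["boxes"][(structure, arm)])
        for plane in PLANES:
            grids = [g[plane] for g in grid_sets]
            for pct in config.percentiles:
                pmap = aggregate_population_map(
                    grids, pct, aspect_ratio=aspects[plane], min_scans=config.min_scans_per_pixel
                )
                stem = f"{structure}_{arm}_{plane}_p{int(pct)}"
                write_map_csv(pmap, out / "maps" / f"{stem}.csv")
                if config.render_png:
                    render_map(pmap, out / "maps" / f"{stem}.png", title=stem.replace("_", " "))
                n_maps += 1

    run_meta = {
        "dirqa_version": __version__,
        "seed": seed_used,
        "settings": {
            "msd_mode": config.msd_mode,
            "hd_percentile": config.hd_percentile,
            "pixel_shape": list(config.pixel_shape),
            "percentiles": list(config.percentiles),
            "min_scans_per_pixel": config.min_scans_per_pixel,
            "stats_mode": config.stats_mode,
            "percentile_rule": "linear interpolation between order statistics",
            "deviation_sign": "unsigned",
            "bounding_box_source": "evaluated structure",
        },
        "counts": {
            "manifest_records": len(manifest),
            "metric_records": len(records),
            "propagated_records": int((records["arm"] != "IOV").sum()),
            "iov_records": int((records["arm"] == "IOV").sum()),
            "failed_records": ev["n_failed"],
            "resampled_pairs": ev["n_resampled"],
            "population_maps": n_maps,
        },
        "cohort_config": config.resolved_cohort().to_jsonable() if config.cohort is not None else None,
    }
    (out / "run.json").write_text(json.dumps(run_meta, indent=2, default=str))
    logger.info("pipeline finished: %s", json.dumps(run_meta["counts"]))
    return out
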