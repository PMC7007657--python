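# dirqa

Quality assurance for automatic deformable structure propagation in
MR-guided radiotherapy of the pelvis.

When a patient is re-planned on a daily MR image, the treatment planning
system deforms the planning scan (CT or MR) onto the image of the day and
carries the delineated structures along. Whether those propagated contours
can be trusted — and whether an MR planning source beats the vendor-default
CT source — is a geometric question: how far do propagated structures
deviate from what an expert would draw on the daily image? `dirqa`
implements the full evaluation pipeline for that question, for physicists
and researchers validating deformable image registration (DIR) workflows:

* **Structure comparison metrics** on 3D binary masks with anisotropic
  voxel spacing:
  - Dice similarity coefficient, DSC = 2|A∩B| / (|A|+|B|),
  - mean surface distance, MSD = the average over surface voxels of the
    Euclidean distance to the other structure's surface (symmetric by
    default, directed mode available),
  - Hausdorff distance, HD = max over both directed surface-distance
    maxima (a percentile variant is available, default 100%),
  plus volumes, connected-component / genus ("pinhole") topology checks,
  all verified against brute-force oracles.
* **Population surface-distance projection maps**: each structure's surface
  deviations are projected onto the transversal, sagittal and coronal
  planes within a bounding box aligned to the patient axes, averaged on a
  fixed pixel grid per scan, then summarised pixelwise as 50th/90th
  percentiles over all scans of all patients — a map of *where* on the
  organ the propagation errors concentrate.
* **Cohort statistics**: per-patient scan averages, population median
  tables per structure and comparison arm (CT→MR, MR→MR, intra-observer
  re-delineation), two-sided Wilcoxon signed-rank tests (exact by dynamic
  programming up to n = 25, including ties; Edgeworth-corrected
  approximation beyond), and a planning-to-daily volume-ratio analysis.
* **A synthetic pelvic cohort generator** reproducing the study design
  end-to-end without patient data: 12 patients × (planning CT surrogate,
  planning MR, 3 follow-up MRs) × 8 structures (prostate, seminal
  vesicles, nodal CTV56, rectum, bladder, femoral heads, penile bulb),
  with CT delineation bias, inter-scan organ variation, arm-specific DIR
  residual error and genus-1 "pinhole" bladder failure cases.

## Worked example

Simulate the default cohort at reduced resolution (64³ voxels over the
same 128×128×160 mm field of view) and run the whole analysis:

```bash
dirqa run-all --out out/demo --reduced --seed 0
```

or equivalently in Python:

```python
from dirqa import CohortConfig, RunConfig, run_pipeline
cfg = CohortConfig.reduced(master_seed=0)
run_pipeline(RunConfig(cohort=cfg, out_dir="out/demo", seed=0))
```

This writes `metrics.csv` (768 rows: 672 propagated structures + 96
intra-observer re-delineations), median tables, volume tables, and 144
population projection maps. The population medians it produced
(`population_medians.csv`, seed 0):

```
metric        dsc               msd                hd
arm         CT_MR   IOV MR_MR CT_MR   IOV MR_MR CT_MR   IOV MR_MR
structure
bladder      0.87  0.98  0.87  3.36  0.42  3.33  9.09  3.20  7.45
prostate     0.87  0.97  0.96  1.75  0.46  0.70  5.52  2.83  2.97
rectum       0.87  0.97  0.95  1.62  0.45  0.76  5.92  3.20  3.27
...
```

Read: MR→MR propagation is consistently more accurate than CT→MR (higher
DSC, lower MSD/HD for every structure) and approaches the intra-observer
variation (IOV), the accuracy ceiling of manual delineation. The paired
Wilcoxon test on the prostate MSD (`table1_msd.csv`) gives medians
1.75 mm (CT→MR) vs 0.70 mm (MR→MR), Δ = 1.05 mm, p ≈ 0.0005 — the
CT-sourced workflow needs significantly more manual editing. The bladder
stands out with large MSD/HD in both arms: its volume varies strongly
between scans and three simulated patients carry genus-1 ("pinhole")
planning bladders that the propagation cannot deform correctly.

`volume_ratio.csv` relates accuracy to the planning/daily volume ratio:
bladder DSC peaks at ratio ≈ 1 and degrades outside the 0.8–1.2 band.

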