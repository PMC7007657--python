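# Methods

This note documents the models, conventions and numerical choices behind
`dirqa`, and what the synthetic cohort does and does not establish about
real patient data.

## Grids, masks and conventions

Structures are binary occupancy masks on regular, possibly anisotropic
voxel grids. Voxel indices are 0-based; the centre of voxel *(i, j, k)*
lies at `origin + index·spacing` (mm). The mapping of array axes to
patient directions (Right–Left, Anterior–Posterior, Cranio–Caudal) is
carried explicitly (default axis 0 = RL, 1 = AP, 2 = CC) rather than
derived from NIfTI orientation matrices, which differ across writers.
All distances are millimetres, volumes cm³. NIfTI-1 is the primary mask
container, NRRD is accepted; DICOM RT-STRUCT contours are out of scope —
the analysis operates on delineated volumes, not contour polylines.

When two masks under comparison live on different grids (the CT surrogate
uses 3 mm slices, MR 1 mm), the coarser mask is resampled onto the finer
grid by nearest neighbour before comparison, and the event is logged. The
choice of the finer grid is a package decision; nothing in the evaluated
design depends on it beyond sub-voxel quantisation.

## Comparison metrics

*Surface* voxels are occupied voxels with at least one face-adjacent
(6-connectivity) background or out-of-grid neighbour; the image boundary
counts as background. Surface distances are Euclidean distances between
surface-voxel centres with anisotropic spacing respected, computed via a
k-d tree and verified exactly against an all-pairs brute-force oracle in
the test-suite.

* DSC = 2|A∩B|/(|A|+|B|). Undefined (raises) for two empty masks.
* MSD: symmetric by default — the mean of the pooled directed distance
  sets of both directions. A directed mode exists; the pipeline logs which
  was used. The symmetric pooled mean was chosen because the underlying
  definition ("average distance between the structures") does not name a
  direction and the symmetric form is exchangeable in its arguments.
* HD: the larger of the two directed maxima. A percentile parameter
  exists but defaults to 100 (the classic, outlier-sensitive worst case);
  no 95th-percentile default is offered on purpose — worst-case behaviour
  is part of what the measure is for.
* The surface-distance target is the nearest *surface voxel centre* of
  the reference, not a sub-voxel mesh: it is consistent between
  implementation and oracle and therefore verifiable to float precision.
  The price is a quantisation of order one voxel diagonal, which is why
  sphere-based analytic checks carry a one-voxel-diagonal tolerance.

Pairs where either mask is empty produce *flagged failure records* rather
than exceptions: failed propagations are findings and stay in the tables.
Topology reports (components, Euler characteristic, cavities, handles via
β₁ = β₀ + β₂ − χ with 6/26-connectivity duality) tag genus ≥ 1 "pinhole"
structures; they never exclude a record.

## Projection maps

For each evaluated structure, a tight bounding box along the patient axes
is placed around its occupied voxel centres (box and surface belong to
the *evaluated* structure; a reference-based mode exists). Each surface
voxel's deviation is projected into the transversal (RL×AP), sagittal
(AP×CC) and coronal (RL×CC) planes by dropping the plane-normal
coordinate; the in-plane coordinates are mapped affinely from the box to
a fixed pixel grid (default 64×64, configurable per structure; the fixed
count is what makes differently-sized organs stackable). Binning is
half-open with the upper edge clamped into the last pixel; a zero-extent
axis maps to pixel 0. Per pixel, deviations are averaged — so
Σ(mean·count) over a grid equals the sum of projected deviations exactly,
a conservation property the tests assert. Deviations are unsigned by
default (a signed inside/outside mode exists but is off).

Population maps take, per pixel, the 50th and 90th percentile of the
scan-level means over all scans of all patients within one comparison
arm, using linear interpolation between order statistics (midpoint median
for even counts). Pixels defined in fewer than a configurable minimum of
scans (default 1) are missing, never zero. Maps are rendered with equal
width and an aspect ratio from the mean bounding-box extents over all
contributing scans; a CSV matrix sidecar carries the exact numbers.

## Statistics

Records are first averaged over each patient's scans per structure and
arm (failed records excluded and counted); population tables report the
median over patients of these patient averages — pooling scans across
patients was rejected because it would weight patients by scan count.
Arm comparisons use two-sided Wilcoxon signed-rank tests on
patient-paired averages at the 5% level, with no multiple-testing
correction (raw p-values are reported). Zero differences are discarded
before ranking (classic Wilcoxon rather than Pratt); ties get midranks.

The exact p-value is computed by dynamic programming over doubled
midranks, which reproduces the full 2ⁿ sign-pattern enumeration
(identical distribution, exact with ties) at polynomial cost; the
enumeration itself serves as the independent oracle in the tests. The
approximate mode is a continuity-corrected normal approximation with
tie-corrected variance plus an Edgeworth fourth-cumulant term
(k₄ = −Σrᵢ⁴/8); without the Edgeworth term the normal approximation
deviates from the exact p by up to 0.04 at n = 12, with it by about
0.001. Both the difference of arm medians and the median of paired
differences are emitted, because the two disagree in general; the
difference of medians is the labelled default.

The volume-ratio analysis relates each propagated structure's accuracy to
`V(planning ground truth) / V(ground truth of the day)` (planning = pCT
for the CT→MR arm, pMR for MR→MR). Ratio effects are analysed on the log
scale, where a multiplicative volume effect is symmetric.

## Synthetic cohort

The generator emulates the study design: 12 patients; per patient a
planning MR, three follow-up MRs and a planning-CT surrogate; 8 pelvic
structures as parametric shapes (ellipsoid prostate and penile bulb,
spherical bladder and femoral heads, a curved-tube rectum, paired lateral
ellipsoids for the seminal vesicles and the nodal CTV56). Sizes are drawn
per patient and per scan from clamped log-normal factors with
structure-specific coefficients of variation (bladder and rectum largest,
femoral heads nearly rigid), centres jittered with clamped Gaussians; the
defaults put planning volumes near published pelvic medians (prostate
≈ 38, bladder ≈ 165, rectum ≈ 75 cm³). Grid default: 1 mm isotropic,
128×128×160; a reduced 64³ preset covers the same physical field of view
for fast tests.

The planning CT is acquired in the same session as the planning MR, so
its anatomy is the pMR state plus a half-strength intra-session
perturbation — not an independent scan draw. On top of that the prostate
is delineated systematically larger on CT (+2 mm margin, applied as an
analytic dilation), and the pCT masks are rasterized on a 3 mm-slice
grid.

**Propagation error model.** The DIR algorithm being evaluated in the
underlying study design is proprietary, so the simulator models only the
observable: the residual deviation of a propagated structure from the
truth of the day. A propagated structure is the zero level set of

    (1 − γ_eff)·SDF(planning) + γ_eff·SDF(daily),

warped by a smooth random residual displacement field (Gaussian noise at
a 20 mm correlation length, per-component SD = the arm amplitude;
CT→MR 2.0 mm, MR→MR 1.0 mm, IOV 0.8 mm). γ_eff is the fraction of the
planning-to-daily anatomical change the registration recovers:

* per arm, γ = 0.70 (CT→MR) and 0.90 (MR→MR) — cross-modality
  registration compensates anatomy worse, which is the effect the
  evaluation is designed to detect;
* multiplied by a Gaussian capacity term `exp(−(ln(V_p/V_d)/0.55)²)` —
  registrations cope with small anatomical differences but not large
  ones, so accuracy degrades away from volume ratio 1;
* γ = 0 for genus-1 ("pinhole") planning bladders (3 of 12 patients by
  default): the propagation failure mode for donut-like structures is
  total.

A plain "warp the planning mask" model was rejected: inter-scan
anatomical variation then dominates both arms identically, the arm
ordering becomes a coin flip for high-variance organs, and the
volume-ratio dependence collapses. The blend model reproduces all three
observables simultaneously — arm ordering, near-IOV MR→MR accuracy, and
the ratio-dependent degradation — from physically interpretable knobs.

Intra-observer re-delineation is modelled as a low-amplitude
short-correlation (12 mm) warp of the planning-MR ground truth. Binary
masks are warped by backward nearest-neighbour mapping, which keeps the
identity and whole-voxel-translation contracts exact. Displacement noise
is synthesised on a coarse lattice (one node per third of the correlation
length) and linearly interpolated — an efficiency device only, since the
field has no energy below the correlation length — then renormalised so
the empirical per-component SD equals the amplitude exactly. All
per-structure transforms run on padded per-structure crops of the grid
(exact, since structures are local). Everything is deterministic under
the master seed via hierarchical seed spawning.

**What the generator does not emulate:** image intensities (no CT/MR
appearance, no registration is actually run), scanner distortion,
observer-specific systematic bias beyond the CT margin, inter-observer
variation, and organ deformation modes beyond size/position change and
smooth boundary warps (no rectal gas pockets, no bladder neck anchoring).
Passing tests therefore establish that the *evaluation machinery* is
correct and that the pipeline recovers designed effects of realistic
magnitude; they do not validate any particular clinical DIR algorithm.

## Problem sizes and runtime choices

The test-suite runs the cohort at the reduced 64³ resolution (identical
physical field of view; metrics quantise at 2–2.5 mm voxels) and uses 20
simulation seeds for the ordering-recovery check; the acceptance script
generates one full-resolution (1 mm) cohort for the design count and uses
5 seeds for the ordering summary. Metric oracles run on random masks up
to 10³ voxels where O(n²) brute force is exact and fast.

## Known limitations

* Surface distances are centre-to-centre between surface voxels; MSD/HD
  carry a quantisation of order one voxel diagonal. Published studies
  rarely state their discretisation, so absolute agreement below the
  voxel scale is not meaningful.
* The population median over 12 patients is noisy for heavy-tailed
  structures (bladder); single-seed orderings can differ from the
  20-seed majority.
* Percentile maps with the default minimum of one contributing scan show
  speckle at the box margins where few surface voxels project.
* The Wilcoxon exact mode is quadratic in the rank total and intended
  for small cohorts (n ≤ ~50); the approximate mode takes over beyond.
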