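# Methods

This note documents the models, numerical choices and known limitations of
`pvsmaps`: a T1w-only perivascular-space (PVS) segmentation pipeline, its
synthetic validation substrates, and the longitudinal burden statistics.

## Segmentation model

PVS are modeled as thin, elongated, hypointense structures embedded in
brighter white matter on T1-weighted MRI. Detection is two-phase:

1. **Intensity phase.** Intensities are normalized to [0, 1] by a robust
   linear map: the 1st and 99th percentiles of brain-mask intensities go to
   0 and 1, with clipping. The map is invariant to any positive affine
   rescaling of the raw intensities, which is what makes dimensionless
   detection thresholds meaningful across scanners. Two local-contrast
   scores are computed per in-domain voxel over a cubic window of radius 2
   (5×5×5, 124 neighbors, center excluded): the median of neighbors minus
   the voxel, and the mean of neighbors minus the voxel. A voxel becomes a
   candidate only if **both** scores pass their thresholds (defaults:
   median 0.1, difference 0.05). The median score is robust to a minority
   of dark neighbors (so a voxel inside a thin tube still registers the
   bright surroundings), while the mean score adds sensitivity to diffuse
   contrast; requiring both suppresses single-score noise excursions. An
   OR combination is available behind a flag for sensitivity analysis.

2. **Morphology phase.** Candidates are grouped into 26-connected
   components (connectivity configurable to 6/18). For each cluster the
   population covariance (divide by N) of voxel coordinates is
   eigen-decomposed; linearity is λ₁/Σλ (in [1/3, 1] for size ≥ 3; sizes
   1–2 are trivially collinear and score 1.0 by convention), and width is
   the larger peak-to-peak extent of coordinates projected on the 2nd and
   3rd principal axes — the stricter reading of "extent perpendicular to
   the first principal component". Acceptance requires size ≥ 5 voxels,
   linearity ≥ 0.8 and width ≤ 15 voxels. Rejection reasons are assigned
   in the fixed order size → linearity → width so reports are
   deterministic. The 5-voxel cluster floor is interpreted in voxels: at
   1 mm³ resolution a 5 mL floor would be 5000 voxels and would exclude
   every PVS, and the optimization grid for this parameter (3–10) confirms
   voxel units.

### Scoring neighborhoods and the search domain

Scoring runs inside a search domain: the skull-stripped brain mask dilated
by two voxels (to reinstate gray matter clipped by stripping), intersected
with parenchyma (cortical GM ∪ deep GM ∪ WM), minus an expanded
ventricular mask (ventricles dilated by three voxels, intersected with the
CSF mask so the exclusion does not invade periventricular WM). Brainstem
and cerebellum are excluded by default when masks are provided — PVS
burden is conventionally reported for the cerebrum — with a flag to
include them.

Score *neighborhoods*, however, are restricted to the brain mask rather
than to the parenchymal domain. The local-contrast operator is defined on
the brain image itself; if neighborhoods were clipped to parenchyma,
voxels on the GM–CSF boundary would be compared only against brighter
interior tissue and partial-volume rim voxels would systematically score
as PVS. With in-brain neighborhoods, dark CSF neighbors pull the local
median down and suppress exactly those rim artifacts. Dilation uses the
6-connected (face-adjacent) structuring element applied iteratively — the
conservative reading of "dilated by n voxels" — configurable to 26.

### Tunable parameters

| parameter | units | default | role |
|---|---|---|---|
| median threshold | normalized intensity | 0.1 | phase-1 contrast floor (robust score) |
| difference threshold | normalized intensity | 0.05 | phase-1 contrast floor (mean score) |
| cluster threshold | voxels | 5 | minimum accepted cluster size |
| linearity threshold | fraction | 0.8 | tube-vs-blob discriminator |
| width threshold | voxels | 15 (fixed) | sheet/plate rejection |
| neighborhood radius | voxels | 2 | scoring window half-width |
| normalization percentiles | % | 1 / 99 | robust intensity anchors |

The preset `clinical` (difference 0.05, median 0.06, cluster 5,
linearity 0.68) reflects thresholds tuned on motion-degraded clinical data,
where a lower median threshold and a looser linearity cut recover faint,
slightly wobbly PVS at the cost of more false positives.

### Threshold optimization

`optimize_thresholds` maximizes mean Dice against manual reference masks
over the four grids (difference and median: 0.02–0.15; cluster: 3–10;
linearity: 0.64–0.9). The default strategy is a single sequential
coordinate sweep in the order difference → median → cluster → linearity,
each parameter fixed at its best-so-far value (parameters not yet swept
stay at defaults); a multi-pass option repeats the sweep to convergence,
and an exhaustive strategy evaluates the full 12 000-combination product.
Ties are broken toward the default value, then the smaller value, so
results are deterministic. Because the intensity scores are
threshold-independent they are computed once per scan; component labeling
is cached per (difference, median) pair and the cluster-level filters are
vectorized over precomputed per-cluster size/linearity/width/overlap
tables, which makes the exhaustive sweep cheap (Dice is reconstructed from
cluster overlap sums, never from re-rasterized masks).

Validation metrics follow the cluster-matching convention: an automated
cluster is a false positive if it overlaps no manual voxel (≥ 1 shared
voxel by default; a minimum-overlap option exists), a manual cluster is a
false negative if no automated voxel lands on it, and per-slice counts
count each accepted cluster once per slice it touches. Dice of two empty
masks is 1.0 (perfect agreement of absence) and is logged when triggered.

## Synthetic phantoms

`generate_phantom` builds a 96³ (default) brain-like ellipsoid: a 2-voxel
CSF shell, a 3-voxel GM shell (intensity 0.45), a WM core (0.7), central
ventricles, and an outer background of zeros. True PVS are straight
cylinders rasterized by distance-to-segment ≤ radius (radius 0.6–1.2
voxels, length 6–25), placed wholly inside eroded WM with a ≥ 2-voxel
Chebyshev gap between structures so each remains a distinct 26-connected
component; a draw whose rasterization fragments into disconnected pieces
(possible for thin oblique lines) or covers fewer than 5 voxels is
redrawn. Spherical distractor blobs share the same intensity drop
(pvs_contrast, default 0.3 below WM) but are non-linear and must be
rejected by the linearity filter. Curved tubes are out of scope: the
linearity filter presumes near-straight PVS.

Image degradation is additive Gaussian acquisition noise followed by
Gaussian smoothing (default FWHM 1.5 voxels). The order matters and is the
physically faithful one for reconstructed MRI: noise enters at
acquisition, and reconstruction/interpolation/partial-volume smoothing
then correlates it, so the noise reaching the detector is spatially
smooth. A white-noise-last model at the same amplitude would produce a
candidate-voxel density of several percent and hundreds of elongated
chance clusters passing the morphology filters — behavior typical of
neither reconstructed images nor the regime this detector targets. No
Rician bias or k-space simulation is attempted, and the phantom has no
cortical folding; sulcal partial-volume false positives of real data are
therefore under-represented, which is precisely why visual inspection
(supported via `edit_segmentation`, with a JSON edit log) remains part of
any real-data workflow. Passing phantom tests demonstrates correct
recovery of tubular structures under noise and blur, not performance on
motion-artifacted clinical scans.

All phantom randomness flows from a single seed through spawned child
sequences (placement and noise independently reproducible).

## Simulated cohorts

`generate_cohort` emulates a two-visit (baseline, week 52) longitudinal
study of 10 subjects by default. A latent per-subject severity drives PVS
burden (baseline cluster count mean 214, SD 90; week-52 decline
proportional to baseline with mean −69 at the mean baseline; volume ≈
11.8 voxels per cluster — the two-visit whole-group burden levels the
statistics are meant to operate on). Outcomes follow linear models with
subject random intercepts and Gaussian noise:

- cognition composite = 120 + β_cog·(PVS volume − 2500) + u_i + ε, β_cog
  default −1.30×10⁻³ per voxel;
- CSF t-tau = 150 + β_tau·(cluster count − 214) + u_i + ε, β_tau default
  2.845 ng/mL per cluster;
- ΔNfL = β_NfL·ΔPVS volume + ε, β_NfL default 1.40.

Covariates (age ~ N(62, 6.5²) years; smoking history Bernoulli(0.4); mean
arterial pressure ~ N(95, 10²) mmHg; time of day uniform over the working
day, per visit) are drawn independently of severity and carry no outcome
effect, so covariate-adjusted fits remain unbiased for the βs — the
cohorts test estimator correctness, not confounding control. Brain-volume
change is drawn per group: progressors (30% of subjects, count rounded)
lose 5.25% ± 0.8 annually and non-progressors 1.24% ± 0.25, truncated on
either side of the 1.8% progression rule so labels and the rule never
disagree. The truncations sit ≥ 2σ from each mean, keeping group-mean bias
well under a standard error at any tested n.

## Burden metrics and statistics

Burden per scan: accepted-cluster count and voxel volume, both also scaled
per 100 mL of WM (the WM-volume adjustment; raw values are always
co-reported since published burden magnitudes appear unadjusted). Brain
volume is GM + WM; percent change is computed from baseline, and a subject
is a non-progressor iff the 52-week decrease is < 1.8% — a decrease of
exactly 1.8% counts as progression (strict reading of "decrease < 1.8%").
Whole-group summary cells are pooled from subgroup means by n-weighted
averaging.

Association models: linear mixed model with fixed effects for the
predictor plus covariates and a per-subject random intercept, fitted by
REML (statsmodels MixedLM); the predictor keeps its raw units while
covariates are standardized (z-scored; encodings: age in years, smoking
ever/never, blood pressure as MAP, time of day in minutes since midnight —
all choices this package fixes, since conventions vary). Wald 95% CIs and
p-values are reported for the predictor. Singular fits raise a clear
error rather than degrading silently. Change analyses compute
within-subject week-52 − baseline deltas (subjects missing a visit are
excluded with a logged count; time-varying covariates enter at baseline)
and fit OLS — with one delta per subject a random intercept is not
identifiable. Non-parametric companions: two-sided Wilcoxon signed-rank
(zeros dropped, exact null for ≤ 25 pairs), Mann–Whitney U, and Spearman
rank correlation. No multiple-testing correction is applied — results
mirror an uncorrected p < 0.05 convention and should be read as
exploratory; this is a deliberate caveat, not an oversight.

## Numerical choices and degenerate inputs

- Masks binarize at > 0.5 on load, with the altered-voxel count logged;
  masks are written as uint8, volumes as float32.
- Geometry mismatches (shape or affine) are errors everywhere — nothing is
  silently resampled. Anisotropic voxels trigger a warning; all morphology
  operates in voxel space.
- Constant images inside the normalization mask, empty WM masks, empty
  scan lists, zero-variance predictors, and all-zero paired differences
  raise descriptive errors.
- Component ordering is lexicographic by smallest voxel index; covariance
  uses population normalization — irrelevant to the linearity ratio but
  fixed so width values are reproducible.
- Scores are computed in float64 and match naive per-voxel loops to 1e-10
  on small grids; voxels with no in-brain neighbors score 0 and are
  counted in the log.
- Every CLI run writes a manifest (parameters, seed, relative output
  paths); identical configuration and seed give byte-identical outputs.

## Problem sizes used in the test suite

Phantom recovery runs at the generator's native 96³ with 8 tubes
(noiseless, and ten noisy seeds at noise SD 0.05); discrimination uses 5
tubes + 5 blobs; grid-search recovery plants a threshold set inside the
default grids on a 64³ phantom (the caching makes the exhaustive
12 000-combination sweep take seconds there); mixed-model calibration uses
100 replicate cohorts of 200 subjects for null-CI coverage and single
cohorts of 500 subjects for parameter recovery, sizes at which Monte-Carlo
error is comfortably below the tested tolerances.

## Known limitations

- The detector is tuned for ~1 mm isotropic T1w contrast; no vesselness or
  Hessian filtering is attempted, so very faint or curved PVS rely on the
  intensity scores alone.
- The phantom does not model cortical folding, bias fields or Rician
  noise; real-data false-positive rates will be higher and visual
  inspection remains necessary.
- Registration, resampling, bias-field correction, DICOM ingestion, and
  tissue segmentation itself are out of scope; the pipeline consumes
  masks produced by external tools (or the phantom generator).
- The intensity-normalization step is this package's addition: the
  detection thresholds are dimensionless and require a unit scale, but
  upstream implementations do not document their intensity conventions.
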