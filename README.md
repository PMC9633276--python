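# pvsmaps

Perivascular spaces (PVS) are CSF-filled channels around penetrating brain
vessels. On T1-weighted MRI they appear as thin, dark, tube-like structures
against bright white matter, and their enlargement is a candidate imaging
marker of impaired glymphatic clearance in neurodegenerative proteinopathies
such as behavioural-variant frontotemporal dementia. `pvsmaps` is a
single-sequence (T1w-only) adaptation of the two-phase MAPS approach to
automated PVS segmentation, together with the downstream burden metrics and
longitudinal association statistics, built for researchers who want to
quantify PVS burden from a clinical-quality volumetric T1w scan plus tissue
masks — and to validate every step on synthetic data with known ground truth.

## The algorithm

**Phase 1 — intensity.** After robust normalization of brain intensities to
[0, 1], each voxel *v* in the search domain is compared with its cubic
neighborhood N(v) (radius 2, center excluded, restricted to the brain):

- median score  m(v) = median{ I(w) : w ∈ N(v) } − I(v)
- difference score d(v) = mean{ I(w) : w ∈ N(v) } − I(v)

A voxel is a candidate iff m(v) ≥ θ_med and d(v) ≥ θ_diff (defaults 0.1 and
0.05). Both scores are positive for dark-in-bright voxels, i.e. PVS-like on
T1w. The search domain is the brain mask dilated by two voxels, intersected
with parenchyma (GM ∪ WM ∪ deep GM) and cleared of an expanded ventricular
mask (ventricles dilated by three voxels ∩ CSF).

**Phase 2 — morphology.** Candidates are grouped into 26-connected clusters.
With λ₁ ≥ λ₂ ≥ λ₃ the eigenvalues of a cluster's voxel-coordinate
covariance, a cluster is accepted iff

- size ≥ θ_cluster (default 5 voxels),
- linearity λ₁ / (λ₁+λ₂+λ₃) ≥ θ_lin (default 0.8), and
- width (max peak-to-peak extent along the 2nd/3rd principal axes) ≤ 15 voxels.

The linearity criterion separates tubular PVS from roundish distractors
(lacunes, noise blobs); the width cap removes sheet-like tissue-boundary
artifacts. Burden is reported as accepted-cluster count and total voxel
volume, raw and per 100 mL of white matter. Thresholds can be re-optimized
against manual reference segmentations by a Dice-maximizing grid search
(sequential coordinate sweep or exhaustive product), and associations
between burden and cognition or fluid biomarkers (CSF t-tau, NfL) are
estimated with linear mixed models (random subject intercept, REML,
covariates: age, smoking history, blood pressure, time of day).

## Worked example

Everything below is runnable without any MRI data; the phantom generator
provides a T1w-like volume with known tubes, tissue masks and ground truth.

```sh
$ pvsmaps simulate-phantom --out demo/phantom --n-tubes 8 --noise-sd 0.05 --seed 42
phantom with 8 tubes written to demo/phantom

$ pvsmaps segment --t1 demo/phantom/t1.nii.gz \
    --brain demo/phantom/mask_brain.nii.gz --wm demo/phantom/mask_WM.nii.gz \
    --gm demo/phantom/mask_GM.nii.gz --ventricles demo/phantom/mask_ventricles.nii.gz \
    --csf demo/phantom/mask_CSF.nii.gz --out demo/seg
8 PVS clusters, 479 voxels

$ pvsmaps validate --phantom-seed 42 --noise-sd 0.05 --out demo/val
dice 0.913, FP 0, FN 0
```

All 8 planted tubes are recovered (FN 0) with no spurious clusters (FP 0);
the voxel-level Dice overlap with the ground-truth mask is 0.913 — voxel
boundaries blur under noise even when every cluster is found. The cohort
simulator plus mixed-model fitter recover a planted t-tau effect
(2.845 ng/mL per PVS cluster) from 100 simulated subjects:

```sh
$ pvsmaps simulate-cohort --out demo/cohort --n-subjects 100 --seed 42
$ pvsmaps stats --cohort demo/cohort/cohort.csv \
    --outcome csf_ttau --predictor cluster_count --out demo/stats --paired
csf_ttau ~ cluster_count [mixed]: beta = 2.835, 95% CI [2.78, 2.889], p = 0 (n_obs=200, n_subjects=100)
Wilcoxon signed-rank on cluster_count: W = 56.5, p = 2.105e-17
```

The estimated slope (2.835) matches the generating effect within 0.4%, and
the paired Wilcoxon test detects the simulated week-52 decline in cluster
count. The same API is available from Python (`pvsmaps.generate_phantom`,
`pvsmaps.segment`, `pvsmaps.fit_mixed_model`, …); every run directory
contains a `manifest.json` recording parameters and seed, and identical
configurations reproduce byte-identical outputs.

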