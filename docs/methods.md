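# Methods

## Overview

`radiomaps` implements a parametric feature-map analysis of prostate T2w
MRI. Instead of computing radiomics features once over a lesion
segmentation, the whole image stack is dissembled into a grid of small
cells (default 2 × 2 × 3 mm, the 3 mm matching the slice thickness), all 93
features are computed per cell, and each feature becomes a spatially
registered parametric map. A lesion VOI drawn on the original image is
transferred into map space and the per-feature map mean is the scalar
read-out. The statistics stage then screens features between clinically
significant (csPCa, ISUP grade group ≥ 2) and non-significant lesions,
fits univariate and PSAD-combined bivariate logistic models with bootstrap
inference, compares AUCs with the DeLong test and quantifies interrater
agreement with ICC(3,1).

## Feature mathematics

93 features in a fixed registry: 18 first-order, 24 GLCM, 14 GLDM,
16 GLRLM, 16 GLSZM and 5 NGTDM, following the standard (IBSI-consistent)
definitions their names imply.

Numerical conventions, chosen to match the reference implementations these
feature names come from:

* **Discretization.** Fixed bin width of 25 intensity units, anchored at
  the patch minimum: `level = floor((x − min)/w) + 1`. A fixed-bin-count
  mode is available. Within-patch binning keeps each cell's texture
  well-conditioned at the cost of inter-cell comparability of absolute
  gray levels; first-order intensity statistics are computed on raw
  intensities and are unaffected (entropy/uniformity use the histogram).
* **Neighborhoods and directions.** All offsets at Chebyshev distance 1
  that fit the patch, unique up to sign for GLCM/GLRLM. Because the
  default cell is one slice thick (3 mm = 1 slice), patches are
  single-slice and the neighborhood degenerates to the in-plane 2D case
  (4 GLCM offset pairs, 4 run directions, 8-connected zones).
* **Degenerate values.** Constant patches: GLCM Correlation and MCC → 1,
  NGTDM Coarseness capped at 10⁶, 0/0 → 0 in Busyness and Strength,
  0·log 0 = 0 (log base 2) everywhere; skewness/kurtosis → 0 at zero
  variance. Patches with fewer than 2 voxels yield NaN for all texture
  families rather than an exception, so border cells stay representable.
  Note that GLRLM RunEntropy and GLDM DependenceEntropy are *not* zero on
  constant patches: run lengths and dependence sizes vary geometrically
  (diagonal line lengths, border truncation) even at constant intensity.
* **GLDM dependence.** A voxel's dependence is the number of neighbors
  within `alpha` (default 0) gray levels; the matrix column index is that
  count plus one (the dependence *size*, including the center), keeping
  small-dependence emphasis defined for isolated voxels.
* **First-order.** Population variance, Pearson (uncorrected) kurtosis
  (Gaussian → 3), Energy with zero intensity shift, TotalEnergy = Energy ×
  voxel volume (mm³).

## Map engine

The grid anchors at the volume origin; a voxel belongs to the cell
containing its center, so cells are contiguous index boxes that partition
the voxel lattice (border cells may be smaller). No resampling is
performed: cells aggregate original-resolution voxels, avoiding
interpolation choices. The grid pitch is the "2 mm adjusted voxel size" of
the map; an overlapping sliding-window mode was deliberately not made the
default (the cells form a partition).

VOI transfer includes a cell when at least `overlap_threshold` (default
0.5) of its voxels are labeled; if no cell qualifies the transfer falls
back to any-overlap, and an empty mask is an error. Extraction is the
arithmetic mean over included cells per feature, NaN cells excluded.

## Statistics

* **Screening.** Two-sided Mann–Whitney U per feature, exact enumeration
  when `n₁·n₂ ≤ 400` without ties, tie-corrected normal approximation
  otherwise. Raw p-values (no multiplicity correction, mirroring the
  apparent-performance design); an optional Benjamini–Hochberg column can
  be enabled.
* **Univariate models.** Unpenalized logistic regression of the csPCa
  label on one standardized feature. The reported model AUC is the
  apparent AUC of the fitted probabilities — by construction ≥ 0.5, since
  the fit orients the score. The orientation-preserving rank AUC
  (`feature_auc`, = U/(n₁n₂), reported as-is and never flipped) is exposed
  alongside; it is the right quantity for null calibration, where the
  folded model AUC is biased upward (~0.53–0.56 under the null at these n).
* **Bivariate models.** Feature plus a PSAD term — continuous
  (standardized) or an indicator at 0.15 / 0.20 (ng/mL)/cm³ — fitted after
  upsampling the minority class to balance (resampling with replacement),
  with a small ridge penalty (λ = 0.01 per average log-loss on
  standardized predictors; invariant to record replication). TZ strata are
  always fitted but flagged low-power when events are scarce.
* **Bootstrap.** Patient-level resampling stratified by class (n = 1000 by
  default), refitting the full specification per replicate; odds ratios
  are exp of the median coefficient, CIs are 2.5/97.5 percentiles, and the
  two-sided p-value is the sign-share 2·min(#≤0 + 1, #≥0 + 1)/(n + 1) — a
  convention with a built-in 1/(n+1) floor, since the resampling
  construction cannot resolve smaller p.
* **DeLong.** Fast midrank implementation of the paired test for
  correlated AUCs; verified against R pROC on a frozen fixture and against
  a permutation oracle. Identical score vectors give p = 1 by convention.
* **ICC(3,1).** Two-way mixed, single rater, consistency:
  (BMS − EMS)/(BMS + EMS) from the ANOVA mean squares, F-test p-value,
  Koo–Li verbal ratings. Consistency form ⇒ invariant to an additive
  rater shift.
* **Operating point.** Youden maximum; ties broken toward higher
  sensitivity. AUC CIs use the DeLong variance. Verbal AUC ratings:
  < 0.70 poor, 0.70–0.80 acceptable, 0.80–0.90 excellent, 0.90–1.00
  outstanding (half-open boundaries).

## Synthetic phantom cohort

The generator reproduces the statistical structure the analysis assumes,
not prostate anatomy:

* **Cohort.** 52 patients by default: noPCa 25 PZ / 8 TZ, ciPCa 4/4,
  csPCa 8/3. PSA and prostate volume are log-normal with group medians
  6 / 7.45 / 9.7 ng/mL and 62 / 47 / 46 mL; log-scale σ derived from the
  interquartile ranges of the cohort the defaults are calibrated to
  (σ ≈ log(IQR ratio)/1.349). PSAD = PSA/volume. noPCa and ciPCa collapse
  to non-csPCa for the binary endpoint.
* **Images.** Background = white Gaussian noise smoothed with a 1-voxel
  kernel, rescaled to mean 300 / SD 60 (arbitrary T2w-like units).
  Default phantom 96 × 96 × 16 voxels at 0.5 × 0.5 × 3 mm; tests and the
  acceptance run use smaller explicit shapes (e.g. 48 × 48 × 6), chosen as
  the package's scaled problem sizes.
* **Lesion.** One ellipsoid per case, in-plane radii drawn from 4–12 mm
  (clipped to fit), z radius 3–6 mm; PZ lesions sit in a posterior band,
  TZ lesions centrally — zone is a label plus a position, no anatomical
  realism. Class contrast is a monotone two-parameter effect in
  background-SD units: a median shift downward (full for csPCa, ×0.35 for
  non-csPCa) plus added local noise (same attenuation). Defaults
  (shift 1.2, contrast 0.8) make csPCa lesions darker with lower 10th
  percentile and higher local contrast. Setting both to zero yields the
  null phantom: lesion voxels are draws from the background process.
* **Raters.** Rater 1 gets the exact ellipsoid; rater 2 a morphological
  perturbation (inner-boundary voxels dropped and outer-boundary voxels
  added independently at rate 0.15), giving Dice > 0.5 by construction and
  extracted-feature ICCs in the excellent range at the defaults.

What the phantom does **not** emulate: MR physics (bias fields, coil
profiles, Rician noise), anatomical zonal structure, lesion infiltration
patterns, scanner/protocol variation. Passing tests therefore demonstrate
the correctness and calibration of the pipeline — not clinical
performance on real T2w images.

## Problem sizes and determinism

All randomness flows from explicit integer seeds through
`numpy.random.SeedSequence` spawning, making every stage byte-reproducible
(NIfTI gzip writes use a fixed mtime). The test suite and the acceptance
script use scaled problem sizes chosen as a deliberate design point:
52-case end-to-end study at 48 × 48 × 6 voxels (12 × 12 × 6 cells), null
calibration with 500 cohorts of n = 200 and 4 features, bootstrap coverage
with 200 runs × 100 replicates, and a 6-case byte-reproducibility run.

## Known limitations

* Apparent (in-sample) performance only; no cross-validation, matching the
  design being reproduced. AUCs from small strata (TZ: 3 csPCa) are
  reported but flagged low-power.
* Per-patch discretization means texture maps are not directly comparable
  across cells in absolute gray-level terms; the analysis uses VOI means
  of each map, which is internally consistent.
* The bootstrap p-value is one convention among several; its resolution is
  bounded by 1/(n+1).
* Single-slice cells make the texture quasi-2D by construction; true 3D
  texture requires a thicker cell or thinner slices.
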