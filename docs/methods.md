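# Methods

This note records the scientific model behind `emphkit`, the numerical
conventions it fixes, what the synthetic phantoms do and do not emulate,
and the design choices made where the underlying procedure was open.

## Densitometry model

Emphysema destroys alveolar walls, lowering local CT attenuation. On a
lung-masked HU volume the package computes:

* **%LAA-950** — 100 · #{lung voxels with HU **strictly below** −950} /
  #{lung voxels}. The boundary voxel at exactly −950 HU is *not*
  counted; densitometry tools differ here, so the convention is fixed
  and tested.
* **Mean lung attenuation** — arithmetic mean HU over the mask.
* **Perc15** — the 15th percentile of lung HU, using linear
  interpolation between closest order statistics (value at sorted
  position 1 + 0.15·(n−1)). Percentile conventions also differ between
  tools; this one is numpy's default and is used consistently for
  Perc15 and all cohort quartiles.
* **TLV** — mask voxel count × voxel volume, in litres.
* **Per-slice LAA curve** — the same strict-threshold fraction per
  axial slice; slices without lung voxels yield a missing value (NaN),
  never a fake zero, and the mask-voxel-weighted mean of the defined
  entries equals the global %LAA-950 exactly (an algebraic identity
  kept as a regression test).

All markers are computed on a 1 mm isotropic grid (trilinear for
images, nearest-neighbour for masks) and always from raw HU. The
[−1000, 400] HU window exists only for visualization and backbone
input; it is a separate operation that never feeds densitometry.

## Weak labeling

A scan is emphysema-positive iff %LAA-950 ≥ 6% (inclusive) **and**
mean lung HU < −850 (strict); %LAA-950 ≥ 14% (inclusive) flags severe
disease. Inclusive/strict boundary semantics follow the wording of the
rule ("≥ 6%", "below −850 HU"); the severe boundary was unspecified and
is taken inclusive for consistency with the primary LAA criterion. The
mean-HU constraint acts as a veto against high-LAA scans driven by deep
inspiration or noise rather than tissue destruction. These are weak
labels — quantitative proxies for training, not radiologist ground
truth.

## Segmentation and QC

The fallback segmenter is a classical pipeline: threshold HU < −320,
remove air components touching the in-plane image borders (outside-body
air; the z faces are kept because the airway may exit the scan range),
keep the two largest 3-D components (one if the runner-up is below 10%
of the largest), morphological closing with a radius-2 ball, per-slice
hole filling. It is deterministic and requires no trained model.
Externally produced masks (e.g. from a U-Net lung segmenter) enter
through the `external` backend and are binarized and regridded to the
volume.

QC measures four plausibility checks — non-empty mask, lung volume in
[0.5, 12] L, mean lung HU in [−1000, −500], axial extent ≥ 10 slices —
and reports pass/fail per check. Bounds are deliberately wide: QC flags
implausible scans, it never drops them (a `--strict` CLI flag turns a
failure into a nonzero exit for pipelines that want gating).

## Patch embeddings

"Mid-lung" is operationalized as the central third of the mask's axial
extent, where parenchyma dominates over apical/basal partial-volume
slices. Nine slices (default) are chosen evenly across the band; each
patch is centred on its slice's lung centroid, padded with −1000 HU,
lung-masked, and sized 224 px (the conventional frozen-backbone input).

The default `texture` backend computes, per patch: a 32-bin intensity
histogram over the unit-windowed patch, a 16-bin gradient-magnitude
histogram, and 16 summary statistics (moments, quantiles, and
below-threshold fractions including the HU < −950 fraction) — 64
dimensions, bitwise-deterministic, no downloads. The optional
`resnet152-gap` backend uses a frozen pretrained ResNet-152's
global-average-pooling output (2048-d); it requires torch plus a local
weights file and refuses to download. Patch vectors are aggregated to a
scan vector by the column-wise mean (max pooling is available but is
not the tested default).

## Modeling

* **Splits** are patient-level, stratified per class, 70/15/15, with
  largest-remainder rounding (ties resolved train → val → test) and a
  per-split patient-id log for leakage audits.
* **Class weights** are inverse-frequency: w_c = N/(2N_c), so the
  weighted sample count always equals N.
* **Feature selection** (training split only, by interface): Welch
  t-tests with Benjamini–Hochberg adjustment ranked by (adjusted p, raw
  p, index), keeping the top 20 by default; L1-logistic selection by
  nonzero coefficients; recursive feature elimination that repeatedly
  drops the 10% of remaining features with the smallest absolute
  standardized L2-probe coefficients.
* **Probes** standardize features with training statistics inside
  `fit` and report coefficients on the standardized scale. `strength`
  is the inverse regularization constant. The L1 strength is chosen on
  the validation split over the grid {0.01, 0.1, 1, 10, 100}, ties to
  the sparser model. An intercept-only probe solves the weighted
  likelihood in closed form (predicted probability = weighted
  prevalence).
* **Fusion** stacks each scan's raw probe logit with [%LAA-950,
  Perc15, TLV], standardizes every column with training-split mean/sd
  only, and fits a class-weighted L2 probe.

## Evaluation

ROC-AUC is implemented as the Mann–Whitney rank statistic (ties count
½); average precision as the step-wise sum over descending unique
thresholds with ties grouped (not trapezoidal); F1 and balanced
accuracy from the 2×2 counts with "predict positive iff p ≥ 0.5"
(inclusive). Confidence intervals are percentile bootstrap at the
patient level: B = 1000 resamples drawn with replacement, metric
recomputed per resample, CI = empirical 2.5/97.5 percentiles.
Resamples on which a metric is undefined (single-class draws) are
redrawn, keeping exactly B values; a bounded redraw budget turns a
pathological configuration into an explicit error instead of a silent
bias. Cluster diagnostics (silhouette, Calinski–Harabasz,
Davies–Bouldin) and PCA are written from the textbook definitions, with
sklearn serving as an independent cross-check in the tests.

## Synthetic phantoms

Each phantom is a chest-like volume on an 84×144×144 grid at
(2, 1, 1) mm spacing (typical LDCT anisotropy): air background at
−1000 HU, a soft-tissue body ellipsoid at +40 HU, and two lung
ellipsoids (≈0.63 L total) of Gaussian parenchyma (sd 25 HU) clipped to
a 5 mm-eroded body so a soft-tissue shell always separates lung air
from outside air. Emphysema is planted as 12 mm-radius spherical blobs
near −980 HU placed uniformly inside the lungs until the fraction of
lung voxels below −950 — counted on the final voxel values, including
the additive 10 HU scanner noise — reaches the requested target, then
everything is clamped to [−1024, 400] HU (which preserves the
below-−950 count). The planted %LAA-950 is therefore exact on the
native grid up to one blob's footprint (≲1.2 points).

Parameter choices worth recording:

* **Structural, not tail-driven LAA.** With a wide parenchyma/noise sd,
  a large share of below-−950 voxels are isolated Gaussian-tail voxels;
  trilinear resampling to 1 mm averages these away almost entirely,
  which would break the generator's guarantee that class labels hold
  with margin after the pipeline's regrid. The defaults (parenchyma sd
  25 HU, noise sd 10 HU, blob radius 12 mm) keep the planted LAA in
  coherent structures that survive resampling to within ≈1.2 points.
* **Residual resampling bias.** Interpolation still erodes blob
  boundaries slightly (the −950 level set lies 81% of the way from
  parenchyma toward the −980 blob value), so 1 mm-grid %LAA-950 reads
  ~5–10% relatively below the native-grid value. Native-grid values are
  the construction truth; the cohort's class margins absorb the bias.
* **Cohorts.** Positives draw target LAA in [8, 30]% with parenchyma
  means in [−890, −860] HU; negatives draw [0, 3]% and [−830, −790] HU.
  The gap between ranges gives every truth label ≥ 1 LAA point and
  ≥ 10 HU of margin against the 6% / −850 HU criteria, so
  label-recovery tests are sharp rather than borderline.

What the phantoms do **not** emulate: airways, vessels, fissures,
lobar anatomy, scanner noise spectra, reconstruction kernels, motion,
or realistic emphysema morphology (centrilobular vs panlobular).
Passing phantom tests therefore demonstrates that the pipeline's
arithmetic, geometry handling and decision logic are correct under
known ground truth — not that any specific clinical accuracy would be
attained on real LDCT cohorts.

## Problem sizes used by the test suite

The suite generates everything at run time: single phantoms for
geometry/densitometry checks, a 40-phantom cohort (prevalence 0.25) for
label recovery and segmentation overlap, and a 120-phantom cohort
(prevalence 0.25) whose per-scan embeddings and markers feed 20
split/training seeds of the probe-vs-fusion comparison. Bootstrap
behaviour is checked with B = 1000 and 500 outer replications of the
mean-of-Normal coverage experiment. These sizes keep the full suite
reproducible on a single CPU in a few minutes while leaving every
statistical check comfortably powered.

## Known limitations

* The fallback segmenter is a heuristic; on real LDCT it will include
  airways and may clip dense pathology. External masks are the intended
  production path.
* The dual-criterion labels inherit all caveats of threshold-based
  densitometry: inspiration level, kernel and dose affect %LAA-950 and
  mean HU; no harmonization is applied.
* The texture backend is a deliberately simple, fully deterministic
  descriptor; it is the test vehicle for the embedding interface, not a
  claim about optimal representation learning.
* Scan-level and patient-level coincide in all generated cohorts (one
  scan per patient); the bootstrap and split machinery nevertheless
  group by patient id and handle multi-scan patients.
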