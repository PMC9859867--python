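# Methods

## Problem

In acute ischemic stroke with a large-vessel occlusion, the quality of the
leptomeningeal collateral circulation strongly conditions outcome and
treatment benefit. An automated collateral ratio

```
CR = 100 % x V_occluded / V_contralateral
```

— the contrast-enhanced vessel volume in the occluded-side middle cerebral
artery (MCA) territory divided by the contralateral volume — replaces
visual collateral grades with a continuous score, but it depends strongly
on *when* the angiographic snapshot is taken relative to the contrast
bolus: a scan a few seconds later can double the CR, and venous-phase scans
can exceed 100 %. This package implements a time-resolved analysis of that
dependency: CR is computed frame-by-frame on a dynamic CT perfusion (CTP)
series, read off at predefined physiological time points, compared with CRs
from three-phase (multiphase) CTA after temporal alignment, and related to
clinical covariates across a cohort.

## Pipeline

Per subject:

1. **Vessel quantification** (`vessels`). Vessels are segmented per frame by
   subtraction thresholding: a voxel in the MCA-territory mask counts as
   vessel iff its enhancement over the pre-contrast baseline (mean of the
   first 2 frames) is at least `enhancement_threshold_hu` (default 50 HU,
   inclusive). This is an intentionally simple, deterministic stand-in for a
   learned vessel segmentation; the function boundary is the plug-in point
   for any other segmenter. Frames with zero contralateral enhanced volume
   yield a *missing* CR (`nan`), never 0 or infinity. The CR is unclamped by
   default — venous-phase CRs well above 150 % are meaningful — with an
   optional `cr_cap`.
2. **Curve extraction** (`curves`). Four time-intensity curve families:
   enhanced vessel volume per side, CR, arterial/venous enhancement (median
   HU over ~3 mm spherical ROIs at the non-occluded carotid top and the
   confluence of sinuses; lower-middle median so the value is an observed
   intensity), and the blood-subtracted arteriovenous (AV) ratio
   `(A - 40) / (V - 40)`, valid only where `V > 40` HU, with negative
   arterial excess clamped to 0. Contrast arrival is the interpolated time
   at which the arterial curve first rises `arrival_delta_hu` (default
   10 HU) above its pre-contrast baseline. A timing-invariant angiogram
   (voxelwise maximum over frames) gives `CR_mip`.
3. **Phase model** (`phases`). The AV-ratio curve is normalized per subject:
   equilibrium (raw ratio = 1, first downward crossing after the peak,
   linearly interpolated) maps to 0 and the curve maximum to 1. Phases on
   the normalized value v: early arterial (upslope, 0.2 <= v <= 1), peak
   arterial (post-peak, 0.5 < v <= 1), equilibrium (0 < v <= 0.5), early
   venous (equilibrium to the post-equilibrium minimum), late venous (after
   the minimum); before the 0.2 upslope threshold or before arrival is
   pre-contrast. Up/downslope is operationalized as before/after the curve
   peak; boundary values belong to the later phase; if the acquisition ends
   before the minimum, the early-venous phase extends to the last sample.
4. **Temporal alignment** (`alignment`). The three mCTA volumes have known
   inter-acquisition delays but an unknown start time. Their AV ratios are
   matched to the CTP AV-ratio curve by exhaustive grid search (0.1 s step,
   linear interpolation, raw ratios, ties to the earliest offset),
   minimizing the summed absolute ratio difference. A flat curve degrades
   gracefully (warning, earliest offset); a manual `--offset` override
   replaces the search for pathological cases.
5. **CR profile** (`timepoints`). Six landmarks — peaks of contralateral
   volume, occluded volume, arterial enhancement, venous enhancement and AV
   ratio (frame-wise argmax, earliest frame on ties, optional centred
   moving-average smoothing used *only* for landmark finding), plus the
   interpolated equilibrium. The CR at a landmark is read from the nearest
   acquired frame (CR is a ratio of segmented volumes and only exists at
   frames). The profile holds these six CRs, `CR_mip`, and the three aligned
   mCTA CRs with their phases: ten CR variables per subject.
6. **Association statistics** (`stats`). Pairwise Spearman correlations
   across the ten CRs (pairwise deletion of missing values; listwise by
   flag), and simple linear regressions of each CR against the ASPECTS-like
   and NIHSS-like covariates. Regressions are *standardized* (both
   variables z-scored, so the slope equals Pearson r and lies in (-1, 1));
   95 % CIs use the t distribution with n - 2 df. Summaries are median and
   IQR with numpy's linear-interpolation quartile convention. Spearman and
   OLS are computed by scipy/statsmodels behind this module's surface.

## Synthetic phantom cohort

No patient data ship with the package; every stage is exercised on a seeded
digital phantom (`synthetic`).

**Geometry.** A 64x64x32 grid at 2x2x4 mm spans a brain-shaped ellipsoid.
Each hemisphere carries a mirrored tree of 7 tubular vessel segments
(radii 2.5–4.5 mm) inside an MCA-territory box mask; mirroring is exact at
the voxel level, so the symmetric phantom is a machine-precision oracle for
CR = 100 %. Each vessel voxel carries a deterministic amplitude factor:
branch calibre (0.45–1.0) times a radial partial-volume falloff shaped so
amplitudes spread smoothly down to 0.3 — without this the segmented volume
would jump all-or-nothing with the threshold and no graded CR could exist.
An arterial blob (carotid top, non-occluded side) and a midline venous blob
(confluence of sinuses) sit outside the MCA masks so ROI sampling never
perturbs the CR.

**Enhancement model.** Arterial enhancement above the 40 HU blood baseline
is a gamma variate `A (tau/(ab))^a exp(a - tau/b)` (peak `A` at
`tau = ab`; defaults a = 3, b = 2 s, A = 350 HU, arrival t0 = 8 s) plus a
shared recirculation term rising from t0 + 12 s toward a plateau of 0.25 A
with a 12 s time constant — the blood-pool equilibrium that keeps late
frames enhanced and pulls the AV ratio back toward 1 (without it the late
venous phase never exists). The venous curve is the arterial bolus delayed
by the arteriovenous transit time (6.5 s) plus a 5 % early arterial
admixture (itself lagging 0.5 s so the pre-transit AV ratio is strictly
decreasing); the 5 % admixture bounds the raw AV ratio near 20. Occluded-
side vessels receive the arterial bolus scaled by the collateral fraction
`cf` (0–1) and delayed by the collateral transit time, averaged over a
7-point uniform spread of route delays (half-width `min(2 s, 0.8 delay)`) —
collateral supply arrives via several leptomeningeal paths — plus the
recirculation term with a saturating flow factor `min(1, cf/0.2)`:
equilibrium contrast reaches any perfused vessel, but none with zero flow.

**Acquisition.** CTP: 30 frames at 2 s over 58 s, i.i.d. Gaussian voxel
noise (default sd 5 HU), all randomness from the config seed. mCTA: three
volumes evaluated from the continuous model at a bolus-tracked offset
(normal, mean 8.1 s after arrival, sd 1.25 s) with ~8 s delays (normal,
sd 0.75 s), matching how scanners trigger on arterial enhancement.

**Cohort.** Per subject: `cf ~ U(0.05, 1)`, collateral delay
`2 + 3(1 - cf)` s (the retrograde route always adds transit time; worse
collaterals add more), random occlusion side, and covariates
`ASPECTS = clip(round(4 + 6 cf + N(0, 1)), 0, 10)` and
`NIHSS = clip(round(25 - 18 cf + N(0, 3)), 0, 42)` — linear links chosen to
span clinically typical ranges so the association stage has recoverable
structure with realistic scatter.

**What the phantom does not emulate.** Patient motion (inputs are assumed
registered), beam hardening, realistic vascular anatomy, partial-volume
effects beyond the radial amplitude profile, flow-dependent washout
asymmetries, and any learned segmentation. Passing tests therefore
demonstrate the *method's* internal correctness — symmetry, timing
recovery, phase-definition fidelity, statistical oracles, determinism —
not clinical performance on real CTP.

## Numerical choices

* Missing/invalid values are `nan` and propagate by pairwise deletion;
  curve consumers skip them.
* Ties: argmax landmarks take the earliest frame; the alignment search
  takes the earliest offset; phase boundaries belong to the later phase.
* The sphere-ROI median uses voxel-centre inclusion and the lower-middle
  convention; cohort quartiles use linear interpolation (the two
  conventions serve different purposes and are documented where used).
* The alignment grid step (0.1 s) bounds the noise-free recovery error;
  search offsets cover the valid AV-ratio range minus the mCTA span.
* Landmark smoothing default is off for noise-free fixtures and a 3-frame
  centred window in the cohort pipeline; stored curves are always raw.
* Problem sizes in tests and in `scripts/acceptance.py` — one 58-subject
  cohort, 100 randomized curves for the phase oracle, 50 + 200 alignment
  trials — are the package's standard demonstration sizes; all complete in
  well under a minute each on one CPU.

## Known limitations

* The subtraction-threshold segmenter under-segments weakly enhancing
  vessels near the threshold; the CR is robust to this only insofar as both
  hemispheres are affected alike.
* With very poor collaterals (cf below ~0.3) the occluded side has no
  segmentable vessel at the arterial peak and early-landmark CRs are
  exactly 0; rank statistics tolerate these ties but the floor compresses
  low-end contrast.
* Temporal alignment assumes the AV ratio is informative at the candidate
  offsets; in the flat late tail the objective is shallow and noisy ratios
  can shift the optimum by seconds (the bolus-tracked acquisition window
  avoids this region).
* The equilibrium landmark requires the AV ratio to cross 1 within the
  acquisition; truncated acquisitions yield a missing landmark rather than
  an extrapolated one.
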