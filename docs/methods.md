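# Methods

This note records the models, conventions and design choices behind
`pelvisop`, and what the synthetic experiments do and do not demonstrate.

## Coordinate frame and orientation decomposition

World frame: X mediolateral (left positive), Y antero-posterior (anterior
positive), Z vertical (cranial positive), lengths in mm, angles in degrees.
A pelvic rotation is decomposed with the fixed intrinsic sequence

    R = Rz(TOP) · Rx(SOP) · Ry(FOP).

Properties that motivated this choice:

* a world-frame rotation about the vertical axis (patient turning in the
  scanner) changes TOP only — SOP and FOP are unaffected;
* for pure sagittal rotations SOP is exactly additive;
* the decomposition is unique away from SOP = ±90°, far outside the
  physiological range; at the gimbal configuration the result carries a
  `degenerate` flag instead of raising.

Positive SOP is *called* anterior tilt throughout; since only a sign
convention is at stake, the package fixes it by the operational rule
"rotation by +θ about +X adds +θ to SOP" and uses it consistently in the
generators, the registration and the phantom protocol.

### Plane orientation is composed additively

Each reference plane carries a canonical orientation frame built from the
landmarks. The orientation of a plane under a pose is defined as the Euler
triple of the *pose* plus the Euler triple of the plane's canonical frame,
not as the decomposition of the matrix product. The two definitions agree
for pure sagittal motion and for planes with zero canonical tilt, but the
matrix-product definition makes the sagittal reading of a tilted plane
(e.g. the sacral-slope plane at ~38.5°) depend on the frontal/transverse
pose in a plane-specific way (≈2° at 15° frontal rotation). The additive
definition is the formalization of "SOP adjusted for the transverse and
frontal orientation": every plane reports exactly the same SOP change
between any two poses, which is also why the phantom protocol's corrected
errors are identical across reference planes.

## Reference planes

* **SSP** — the S1 superior endplate plane; its sagittal angle is the
  sacral slope.
* **APP** — through both ASIS and the pubic symphysis; vertical (SOP ≈ 0)
  in the canonical pose.
* **PTP** — through the hip-center axis and the pubic symphysis. (A plane
  through the ASIS axis and the symphysis is *identical* to the APP for
  every landmark set, so it cannot serve as a distinct definition; the
  hip-axis-to-symphysis line is a classical sagittal tilt proxy.)
* **X1/X2** — configurable registry slots, defaulting to the
  PSIS–PSIS–symphysis plane and the iliac-crest/ischial-tuberosity plane.

All sign/orientation choices (which way a normal points, which in-plane
axis is "up") are resolved against *intrinsic* references computed from the
landmarks (ASIS axis, ASIS-mid minus PSIS-mid, hip-center midpoint to
iliac midline), never against world axes. Consequence: the 18 morphological
parameters (13 distances, 5 angles, including pelvic incidence and the
sacral-pubic angle) are exactly rigid-invariant, which the suite tests at
1e-9 under random rigid transforms.

## Registration model

Both views are orthographic projections sharing the Z axis — AP keeps
(x, z), lateral keeps (y, z). Real biplanar slot scanners have no vertical
distortion and a mild horizontal fan; the orthographic model is a declared
simplification, adequate because the acceptance quantity is an orientation
*error* relative to a neutral reference measured with the same model.

* **Pre-registration**: Levenberg–Marquardt least squares of projected
  landmark residuals over the 6-DOF pose (rotation vector + translation),
  initialized in closed form (Kabsch) from picks visible in both views.
  Each pick contributes up to four scalar constraints; fewer than three
  picks raises an under-constrained error.
* **Refinement**: Nelder–Mead over a 6-vector of pose offsets (degrees/mm)
  minimizing the mean squared distance from projected model silhouette
  samples to the nearest picked contour point (KD-trees per view), capped
  at 500 iterations, simplex tolerance 1e-4. The published workflow refines
  manually; the contour objective is an automatic stand-in whose adequacy
  is judged by the phantom protocol, not by claim of equivalence. The
  result never has a larger objective than its starting pose.
* **ICP**: nearest-neighbour correspondence alternated with the closed-form
  rigid fit, RMS change < 1e-6 mm or 200 iterations; used for transferring
  a cup reconstruction between bone models.

## Phantom protocol

The physical trunk phantom is replaced by the synthetic template pelvis;
manual landmark picking is emulated by isotropic Gaussian 2D pick noise
(σ = 0.5 mm by default — an assumption, the published protocol does not
report pick precision). 19 orientations (ΔSOP/ΔTOP grid, two ΔFOP = ±15°
poses, ΔSOP = ±30° extremes), 5 repeats each. Because a physical reference
is impossible without damaging a phantom, the protocol's reference is the
mean of the neutral-pose measurements; corrected error =
measurement − neutral mean − ΔSOP. With zero noise the protocol is exact to
registration tolerance (< 1e-9°); with 0.5 mm noise the pooled mean
absolute corrected error is ≈ 0.19° (pick noise is the only modeled error
source; a human operating real hardware faces more).

## Synthetic cohorts

The generator is the study-condition definition, not a fitting device:

* Published marginals (age, height/weight by sex, supine SOP) are drawn
  from *mean-calibrated truncated normals*: the parent location is solved
  so the truncated mean equals the configured mean (plain truncation of
  N(38.5, 8.3²) to [15.0, 57.3] would shift the mean by −0.2°, which the
  marginal-fidelity requirement cannot absorb). The realized SD is then
  slightly below the parent SD (8.3 → ≈7.9 for supine SOP).
* Standing SOP = supine + independent N(−0.8, 5.2²), reproducing the
  published standing SD ≈ 9.8° given the supine SD; no further correlation
  structure is modeled. Derived quantities (standing SOP, response) are
  not truncated.
* LLA ~ N(48.4, 10²). The mean is the calibration that makes the
  scenario-B generating model's implied postoperative mean equal 34.7°,
  hence an implied standing-to-postoperative change of −3.0°; the test
  suite re-derives this by brute force at n = 100000.
* Residual σ (4.8° / 3.6° per scenario) is deliberately identified with
  the reported oneSE cross-validation RMSE of each scenario.
* Morphological and range-of-motion columns are nuisance predictors:
  independent of the response (morphology: 5% CV around the template's
  values; ROM: declared plausible preoperative distributions). L5-S1
  fusion prevalence 8%, no effect on the response.
* Scenario A exposes 31 predictor columns, scenario B 33 (adds standing
  SOP and LLA); counts are enforced by the registries.

What passing tests show: the pipeline recovers the generating coefficients,
the selection machinery finds the correct support, and the measurement
chain is unbiased under the stated noise model. What they do not show:
performance under real EOS geometry, real landmarking error structure,
inter-subject anatomical variation, or any correlation between morphology
and pelvic mobility — none of which the generator emulates.

## Penalized selection

* Predictors are standardized to unit SD (response centered) inside every
  fit — including inside each LOOCV training fold — and coefficients are
  reported back on the original scale.
* λ grid: 100 log-spaced values from λ_max (all-zero solution) down to
  1e-4·λ_max.
* The solver is a Gram-based cyclic coordinate descent (numba-jitted),
  warm-started along the grid and across LOOCV folds from the full-data
  path. Once the sign pattern of a solution stabilizes, the exact KKT
  system on the active set is solved and verified; this removes the slow
  tail of first-order convergence at the dense end of the path. Agreement
  with an independent implementation of the same objective is at 1e-7 on
  random designs (test), and the λ = 0 limit matches the normal equations.
* LOOCV SE is the per-observation definition: SD of the n squared
  prediction errors divided by √n.
* The four-model family: `max` (smallest λ), `minMSE`, `oneSE` (largest λ
  with MSE ≤ min + SE), `min` (largest λ with exactly one surviving
  coefficient; if the grid skips all singleton supports, the smallest
  non-empty support at its largest λ). Coefficients below 1e-3 in
  magnitude are dropped from supports.
* Reported coefficients/SEs/p-values are *post-selection OLS refits*
  (penalized estimates carry no standard errors); LOOCV RMSE of a refit
  uses the hat-matrix identity. p-values are classical, not
  selection-corrected — they describe the refit, as in the source results.
* Nested comparisons: Gaussian likelihood-ratio test
  (ℓ = −n/2·(ln(2π·RSS/n) + 1)), ΔAIC/ΔBIC = criterion(smaller) −
  criterion(larger) so positive values support the larger model; support
  labels at ΔAIC > 4.6 ("moderate") and > 13.8 ("very strong").

## Safe zones

Generic cone-impingement model: a cup orientation is safe when the neck
axis stays within the free cone of half-angle OA/2 about the cup axis for
every required motion arc (sampled every 2°), with
OA = 180° − 2·arcsin(neck/head). Neck geometry follows the CCD angle and
stem anteversion; radiographic (Murray) cup angles in the APP frame; a
right hip is modeled. Default required ROM: flexion 130°, extension 40°,
internal rotation at 90° flexion 40°, external rotation 40° — declared,
configurable defaults. A motion required with zero amplitude imposes no
constraint. Tilt uncertainty: the zone is recomputed with the pelvis
(and the bone-fixed cup) tilted by each offset in a set such as
{μ−kσ, μ, μ+kσ} and the masks intersected; the reduction is reported as a
percentage of the nominal zone. With the defaults the reduction grows
strictly with the uncertainty width (≈13% / 25% / 35% at ±4°/±8°/±12°
around −3°). The published safe-zone construction this mirrors is a
proprietary, differently-parameterized zone, so only the qualitative
behaviour (monotone, substantial shrinkage) is comparable, not the
percentages.

## Numerical conventions and degenerate inputs

* Rotations validated to orthogonality/det at 1e-8; plane frames at 1e-9.
* Collinear plane-defining points raise `DegeneratePlaneError`; missing
  landmarks raise `MissingLandmarkError` carrying the missing names.
* Sample SD uses the n−1 denominator everywhere; descriptives print as
  "mean (SD, min to max)".
* Identical paired samples return t = 0, p = 1 (the limit of the paired
  test, where the generic formula is 0/0).
* All randomness flows through `numpy.random.default_rng` seeds; cohort
  generation is byte-reproducible, and the acceptance script derives all
  sub-seeds from its single `--seed`.

## Problem sizes

Defaults were chosen so the full pipeline runs comfortably on one CPU:
phantom protocol 19 × 5 (< 1 s), cohort generation n up to 1e5 (~1 s),
coefficient-recovery fits at n = 5000, model-family selection at n = 1000
(~9 s per cohort, 1000-fold LOOCV × 100 λ), safe zones on 2° grids.

## Known limitations

* Orthographic projection ignores the horizontal fan beam of real biplanar
  scanners; no intensity-based (DRR) registration.
* Pick noise is the only measurement error source; no segmentation error,
  no metal artifacts, no soft-tissue occlusion.
* The cohort generator models marginals and a linear response, not joint
  anatomy; morphological parameters are drawn, not computed from per-
  subject geometry.
* Post-selection inference is uncorrected, as in the mirrored analysis.
* The safe-zone model omits bony impingement and edge-loading constraints.
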