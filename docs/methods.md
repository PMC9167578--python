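# Methods

This note documents the models, numerical choices and limitations behind
`tendonmech`, in the spirit of a package methods appendix. Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Coordinate conventions and units

Right-handed world frame in millimetres; image pixels indexed (row, column)
from the top-left, with per-axis pixel spacing in mm/px carried by the
calibration transform; quaternions stored scalar-last (x, y, z, w). Units
are fixed throughout: mm, mm², ml (1 ml = 1000 mm³), N, N·m, s, Hz. Strain
is stored as a fraction and rendered as percent only in reports, which keeps
Young's modulus in MPa with no hidden factors of 100.

## Geometry reconstruction

* **Pixel-to-world.** Composition of the calibration (pixel scaling + rigid
  image-plane→probe transform) and the frame pose (probe→world). The map is
  an isometry up to the pixel-spacing scale; rotations are validated
  orthonormal to 1e-6. The calibration is treated as a validated input —
  estimating it from phantom scans is out of scope.
* **Length.** Straight chord between the two landmark points (two-point
  method), not a curved arclength. The generator's default phantom has a
  straight centerline, matching the near-straight free Achilles tendon this
  convention presumes.
* **Slice stations.** The projection of each contour centroid onto the
  landmark chord. This supplies the ordering the volume integral needs;
  stations must be strictly increasing (slices are sorted first, exact
  duplicates are an error).
* **CSA.** Vector shoelace area about the centroid of each contour —
  orientation-independent and exact for planar polygons. Contours must be
  planar within 0.5 mm (the axial/lateral imaging resolution) of their
  best-fit plane and simple (checked by projecting onto that plane).
* **Volume and mean CSA.** The CSA profile is linearly interpolated between
  stations and integrated with the trapezoidal rule (default 0.1 mm grid;
  exact for linear profiles). Mean CSA is the same integral divided by the
  station span, so `mean_csa × span / 1000 == volume` is an exact identity
  rather than an approximation. Proprietary surface-interpolation schemes
  used by acquisition software are intentionally not emulated; for
  near-convex tendon cross-sections the difference is below the package's
  1% phantom-recovery tolerance.

## Synthetic-data generator

The generator defines the study conditions; downstream code never sees
ground truth except through it.

* **Phantom.** Tubular, polynomial CSA profile in normalized arclength
  (constant / linear taper / quadratic, positivity checked), closed-form
  volume. Sweeps place one frame per 0.1 mm by default (the acquisition
  frame spacing), with circular contours sampled at 64 vertices. An
  inscribed 64-gon underestimates the circle area by sin(2π/64)·32/π ≈ 0.16%,
  which is the dominant term in the noiseless volume-recovery error.
* **Pose noise.** Isotropic Gaussian translation jitter and small-angle
  rotation jitter per frame. The default noisy-study value is σ = 0.133 mm
  per axis, chosen so that ~99.7% of reconstructed point errors lie within
  ±0.4 mm, the validated point-reconstruction accuracy of calibrated
  freehand systems.
* **Subjects.** MVIC torque uniform 80–160 N·m, moment arm normal
  43.3 ± 3.93 mm, resting length 40–70 mm, resting CSA 40–65 mm²,
  true stiffness uniform within a 200–600 N/mm physiologic band; loaded
  length follows the linear stiffness model
  `L(f) = L₀ + F(f)/k` with `F(f) = f·MVIC/arm`.
* **EMG.** Raw EMG is band-limited (20–450 Hz) Gaussian noise amplitude-
  modulated so its RMS envelope equals the programmed envelope. Dorsiflexion
  trials ramp the envelope and emit torque via the subject's true linear
  co-contraction law; staged plantarflexion trials ramp (default 1 s) to the
  target fraction of MVIC and hold, emitting *net* torque (true minus
  antagonist) plus the co-contraction EMG. 1000 Hz sampling, 8 s default
  duration.
* **Crossover trial.** 16 subjects × 3 interventions × pre/post. Baselines:
  volume 2.2 ± 0.6 ml, stiffness 330 ± 60 N/mm, within-subject correlation
  0.9 across sessions (measured tendon properties are highly reliable
  between sessions). Intervention change means are calibrated to the
  reported cohort (volume −0.30 / −0.05 / −0.12 ml and stiffness −67.35 /
  +37.78 / −36.45 N/mm for the 8 s–75%, 2 s–75% and 8 s–35% arms); change
  SDs are 0.13 ml (reproducing standardized pairwise effect sizes ≈ 2 and
  1.4 for volume) and 40 N/mm (consistent with a stiffness MDC ≤ 45 N/mm).
  Period order is a seeded random permutation per subject; no carryover is
  modelled (the one-week washout is assumed complete).

What the generator does **not** emulate: speckle-level B-mode texture,
segmentation error shaped by image quality, fatigue or viscoelastic creep
within a session, heteroscedastic torque noise, and period (week) effects.
Passing tests therefore demonstrate correctness of the measurement and
inference chain under the stated error model, not robustness to every
failure mode of real acquisitions.

## Signal processing and force chain

* **Filter.** 4th-order Butterworth band-pass, applied forward–backward
  (zero phase) so the envelope stays aligned with torque. The band edges are
  20–450 Hz; the upper edge must stay below Nyquist.
* **Envelope.** RMS over a centred 200-sample sliding window, shrinking at
  the edges (same-length output).
* **Co-contraction fit.** Ordinary least squares on samples pooled across
  the (up to three) dorsiflexion trials, time-matched envelope vs torque.
  Note a deliberate property of the full chain: filtering the amplitude-
  modulated EMG removes a little modulation-sideband power, so the estimated
  envelope is a few percent smaller than the programmed one and the fitted
  slope correspondingly larger. Because the *same* envelope estimator feeds
  the correction at prediction time, the scale factor cancels — predictions,
  corrected torque and tendon force are unbiased (the scale-consistency
  property is tested). Chain-level envelope recovery is held to 5%.
* **MVIC rule.** Peak per trial from a 0.5 s moving-average plateau; the
  maximum is accepted only when the two highest peaks are within 10%.
* **Plateau for staged levels.** Mean corrected torque over the central
  portion (40–90%) of the hold, comfortably past the 1 s ramp.
* **Force.** Corrected torque / (moment arm in metres); the moment arm is
  `d1 − d2 > 0` by construction.

## Mechanics

Free-intercept OLS for both stiffness and modulus (no origin constraint —
the measured force–elongation line need not pass through zero because of
resting tension and measurement offsets). Two repeat scans per state are
averaged before differencing; elongations use the actual corrected force at
each level (nominal %MVIC force is available by constructing the points
explicitly). Small negative elongations are flagged with a warning, not
clamped. The identity `E = k·L₀/A₀` holds to machine precision because
stress/strain are linear rescalings of force/elongation.

## Statistics

* **ANOVA.** Balanced two-way fully-within-subjects sum-of-squares
  decomposition; each effect is tested against its own subject-interaction
  stratum. Sphericity is assumed (no epsilon correction) and pairwise tests
  are unadjusted, matching common practice for this design; the
  implementation is verified against statsmodels `AnovaRM` to full float
  precision in the tests. The decomposition is vectorized over replicates,
  which is what makes the 2000-replicate null calibration cheap: the
  interaction test's empirical type-I error at α = 0.05 is computed in the
  acceptance suite.
* **Contrasts / simple effects.** Paired t-tests on per-subject change
  scores; effect size = difference of mean change scores / pooled (n−1)
  change-score SD.
* **Normality.** One-sample KS against a normal with estimated parameters,
  Lilliefors-corrected p (parameters are estimated, so the plain KS null
  distribution would be anti-conservative).
* **ICC.** Two-way mean-squares decomposition; both the consistency form
  (classically "ICC(3,1)") and the absolute-agreement form are computed.
  Absolute agreement is reported by default — the conventional label and the
  stated agreement type conflict in parts of the applied literature, so both
  numbers are always available. CIs are F-based (exact for consistency,
  McGraw–Wong Satterthwaite approximation for absolute agreement), verified
  against pingouin.
* **SEM / MDC.** `SEM = pooled SD × √(1 − ICC)`; `MDC = SEM × 1.96 × √2`.
* **Sample size.** Normal-approximation paired formula
  `n = (z₁₋α/₂ + z₁₋β)² · 2(1 − ρ) / ES²`, reported together with the
  formula string, because published crossover sample sizes are often not
  reconstructible without knowing the exact convention used.

## Problem sizes and tolerances

Defaults used by the test and acceptance suites: 0.1 mm frame spacing and
64-point contours for phantom-recovery checks (1% volume tolerance); 0.5 mm
spacing for noiseless full-chain checks (0.5% stiffness tolerance) and 2 mm
spacing for the 100-replicate noisy-recovery study (bias < 2%; length comes
from the landmark chord, so coarse spacing does not degrade it); 2000
replicates for the type-I error of the interaction test (0.05 ± 0.02); 200
replicates of 200 × 2 tables for ICC bias (< 0.02). Exact identities
(modulus, mean-CSA×span, MDC) are asserted at 1e-9 relative or tighter.

## Known limitations

Linear force–elongation model only (no toe-region nonlinearity or
viscoelastic creep); straight-chord length; area (not surface) interpolation
for volume; no automatic segmentation or landmark detection; RM-ANOVA rather
than mixed-effects models (period effects ignored in the primary analysis);
the generator's intervention effects are homoscedastic and Gaussian.
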