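# tendonmech

Analysis toolkit for acute tendon-loading experiments that measure the free
Achilles tendon with **freehand 3D ultrasound**: reconstruction of tendon
length, cross-sectional area (CSA) and volume from tracked, segmented sweeps;
EMG-based antagonist co-contraction correction of dynamometer torque; tendon
force, force–elongation **stiffness** and stress–strain **Young's modulus**;
and the repeated-measures statistics of a randomized crossover trial that
compares isometric loading protocols. A synthetic-data generator produces
every input with closed-form ground truth, so the whole chain is testable
without any ultrasound or dynamometer hardware.

## Who this is for

Researchers in musculoskeletal biomechanics who quantify acute changes in
tendon morphology (volume, CSA) and mechanics (stiffness, modulus) after
loading interventions, and who need a transparent, reproducible version of
the standard measurement chain with verifiable error properties.

## The measurement model

**Geometry.** A tracked sweep is a sequence of B-mode frames; each frame has
a probe pose (rigid transform to the laboratory frame) and a manually
segmented cross-section contour in pixel coordinates. A pixel `(r, c)` maps
to the world as

```
x_world = R_pose (R_cal s(r, c) + t_cal) + t_pose
```

with `s` the pixel-spacing scaling and `(R_cal, t_cal)` a validated spatial
calibration. Free-tendon length is the straight-line distance between the
two anatomical landmarks (calcaneal notch, soleus muscle–tendon junction;
two-point method). CSA is the shoelace area of each planar contour; volume
is trapezoidal integration of the linearly interpolated CSA profile along
the tendon axis (1 ml = 1000 mm³); mean CSA is that integral divided by the
station span, so `mean CSA × span = volume` exactly.

**Force.** Net plantarflexion torque underestimates true torque when the
tibialis anterior co-contracts. During maximal dorsiflexion trials the
TA EMG (band-passed 20–450 Hz, RMS-enveloped over 200 samples) is regressed
on dorsiflexion torque, `torque = P1·envelope + P2`; during plantarflexion
the predicted antagonist torque is added back, and tendon force is the
corrected torque divided by the tendon moment arm (`d1 − d2` from the
two-distance B-mode method).

**Mechanics.** With tendon force and elongation at 35/55/75% of maximal
voluntary isometric contraction (MVIC), stiffness `k` is the OLS slope of
the force–elongation line and Young's modulus `E` the slope of the
stress–strain line; for linear fits on the same points `E = k·L₀/A₀`
exactly.

**Statistics.** The crossover trial is analysed with a 2 (time: pre/post) ×
3 (intervention) fully-within-subjects ANOVA (`CrossoverAnova(...).fit()`),
with pairwise interaction contrasts and simple effects on change scores,
standardized effect sizes (difference of mean change scores / pooled
change-score SD), and reliability metrics: ICC (two-way, absolute-agreement
and consistency forms), CV, SEM and the minimal detectable change
`MDC = SEM × 1.96 × √2`.

## Worked example

```python
import tendonmech as tm

# 1) phantom with known volume, scanned and reconstructed
phantom = tm.make_phantom(50.0, ("linear", 60.0, 40.0))
sweep = tm.simulate_sweep(phantom, frame_spacing_mm=0.1, seed=0)
geom = tm.reconstruct_geometry(sweep)
print(f"true volume {phantom.true_volume_ml:.3f} ml, "
      f"reconstructed {geom.volume_ml:.3f} ml")

# 2) stiffness via the full chain for one simulated subject
subject = tm.SimulatedSubject()
meas = tm.pipeline.measure_subject(subject, seed=1, frame_spacing_mm=0.5)
print(f"fitted stiffness {meas['stiffness_Nmm']:.1f} N/mm "
      f"(truth {subject.true_stiffness_Nmm:.1f})")

# 3) crossover trial statistics
data = tm.simulate_crossover_dataset(16, seed=42)
res = tm.CrossoverAnova(data, "volume_ml").fit()
ia = res.interaction
print(f"interaction F({ia.df_num},{ia.df_den}) = {ia.F:.2f}, p = {ia.p:.2g}")
print(res.simple_effects(mdc_threshold=0.1).round(3))
```

prints

```
true volume 2.500 ml, reconstructed 2.496 ml
fitted stiffness 330.0 N/mm (truth 330.0)
interaction F(2,30) = 11.11, p = 0.00024
              pre_mean  post_mean  mean_change  pct_change       t      p  within_measurement_error
intervention
2s75             2.182      2.108       -0.074      -3.390  -1.959  0.069                      True
8s35             2.201      2.105       -0.097      -4.391  -2.196  0.044                      True
8s75             2.163      1.849       -0.314     -14.532 -10.881  0.000                     False
```

The tapered phantom's 2.5 ml analytic volume is recovered to 0.2%; the
noiseless measurement chain returns the subject's true stiffness; and in the
simulated 16-subject crossover the time-by-intervention interaction is
tested on (2, 30) degrees of freedom. The simple-effects table shows the
expected response pattern: a large (~14%) volume reduction after the
long-duration/high-intensity arm (`8s75`), and changes below the 0.1 ml
minimal detectable change for the other two arms.

A CLI mirrors the library:

```bash
tendonmech simulate sweep --length-mm 50 --out sweep.json
tendonmech reconstruct --sweep sweep.json
tendonmech simulate dataset --n-subjects 16 --out trial.csv
tendonmech stats anova --data trial.csv --outcome volume_ml
tendonmech run-all --seed 1 --out results_dir
```

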