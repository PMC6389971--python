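# Methods

This document records the forward model, the estimation choices and the
numerical conventions behind `cardimu`, plus the limitations we know about.

## Forward model

### Kinematics

The sensor is modelled as rigidly attached to the epicardium near the apex.
Per heart cycle it undergoes

- a rotation `θ(t)` about the heart's long axis (sensor x), and
- a translation `p(t)` with components along the long axis (x),
  circumferential (y) and radial (z) directions,

both shaped as a C¹ piecewise raised-cosine pulse that rises from 0 at the
R-peak to its peak at end-systole and returns to 0 at the cycle end. The
waveform and its first two derivatives are analytic, so gyro and
accelerometer channels are generated without numerical differentiation and
the ground truth (θ, p, the end-systolic sample) is exact.

End-systole is placed by a fixed quadratic regression of the R-to-dP/dt_min
delay on heart rate,

```
t_es(HR) = 0.61 − 4.317·10⁻³·HR + 1.05·10⁻⁵·HR²   [s]
```

treated as a calibration constant (its refit would need invasive pressure
data). It is used both by the simulator and by the analysis, clipped to
[0.05 T, 0.9 T] inside a cycle of length T and flagged outside 30–250 bpm.

### Gravity

Gravity enters as the accelerometer's reaction to it. With `inclination`
the angle of the long axis from the vertical (0° → the rotation plane is
horizontal and rotation never changes the gravity projection; 90° → supine,
maximal artifact), the cycle-start body-frame gravity reaction is

```
v = (g·cos(incl), 0, −s·g·sin(incl)),   g = 9.81 m/s², s = artifact_sign
```

and the measured acceleration is `acc(t) = Rx(−θ(t))·(p̈(t) + v)`. The
cycle-varying part of the gravity projection scales with `sin(incl)` and,
for θ ≈ 10°, reaches ≈ 1.6 m/s² — the mechanism by which static
compensation overestimates displacement. `artifact_sign = +1` is defined
*behaviourally*: the gravity artifact adds to the true circumferential
displacement at end-systole (internally this requires the negative radial
gravity component, because double integration maps a positive acceleration
pulse into a negative displacement excursion at ES).

### Pressure, strain and regional work

LV pressure is a half-cosine rise/fall pulse whose steepest fall (dP/dt_min)
lands exactly at `t_es`. Segment strain uses two unit shapes: healthy
(shorten to ES, hold, re-lengthen during filling) and ischemic (isovolumic
lengthening bulge plus post-systolic shortening peaking after ES). Because
the pressure–strain loop area is linear in the strain amplitude, the
amplitude is calibrated with a single division so that one noiseless
cycle's loop area equals the intervention's work target exactly — no
iterative tuning. Work targets implying peak strain beyond ±95% (possible
only with extreme cohort variability draws) are capped with a warning,
since strain below −100% would mean non-positive segment length.

### Interventions and cohorts

Four intervention parameter sets are shipped (`REFERENCE_PARAMS`): baseline,
ischemia, dobutamine, and dobutamine + ischemia, each fixing heart rate,
ED→ES rotation, displacement amplitudes, systolic pressure and the work
target. A reperfusion set (baseline-like) exists but is not part of the
default protocol, whose per-arm subject counts are 11/11/4/4.

Biological variability is lognormal per quantity family (rotation,
displacement, work, heart rate, pressure). Each family's target SD is split
into **equal-variance subject and recording components** (σ/√2 each): a
pure per-subject multiplier would keep each subject's ischemia/baseline
ratio constant and make classification trivially perfect. `re_sd_scale`
scales both components. Even so, at the default scale the synthetic cohort
separates perfectly (all AUC = 1.0) — the generator is calibrated to the
reference group means, which are far apart relative to within-subject
spread. Analyses that need a non-saturated task should raise
`re_sd_scale` (the cohort example uses 2.0).

Noise defaults: white accelerometer noise 0.05 m/s², white gyro noise
0.005 rad/s plus a constant 0.002 rad/s bias, LV pressure 0.2 mmHg, segment
length 0.002 mm; ECG is noiseless by default. Sampling rate 700 S/s.

## Estimation choices

### Static compensation (STAc)

Subtract the per-axis mean acceleration over the cycle. Exact when the
sensor does not rotate; otherwise the cycle-varying gravity residual
survives into the double integral.

### Dynamic compensation (DYNc)

1. Integrate the gyro to an orientation track: per-sample rotation-vector
   exponential with midpoint angular velocity,
   `Φ_{k+1} = Φ_k · exp([½(ω_k + ω_{k+1})Δt]ₓ)`. Composing exact rotation
   operators keeps the track orthonormal by construction.
2. Fit the cycle-start gravity vector from the identity
   `mean_t(Φ_tᵀ)·g₀ = mean_t(acc)` (motion acceleration has ≈ zero mean
   over a whole cycle), rescaling `‖g₀‖` to 9.81 m/s² to absorb
   accelerometer scale error. A near-singular mean rotation raises an
   error rather than returning an ill-conditioned estimate.
3. Rotate the measured acceleration into the cycle-start frame, subtract
   g₀, and remove the residual per-axis mean.

The final mean removal makes DYNc degenerate *exactly* to STAc when the
gyro is identically zero, and keeps the output insensitive to small
gravity-fit residuals. The output frame is the cycle-start frame; over a
≤ 10° excursion the difference from the body frame is second-order.

### Integration and rotation traces

Displacement: trapezoidal integration to velocity, a linear ramp
correction pinning end-of-cycle velocity to zero (the heart returns to its
starting position each beat), trapezoidal integration to displacement, and
a second ramp correction. Each cycle is integrated independently so drift
cannot accumulate across beats. Rotation: subtract the per-cycle mean
angular velocity (absorbs constant gyro bias and enforces cyclicity), then
trapezoidal integration, reported in degrees.

### End-systolic motion and 3D reduction

ESM is `|trace(t_es) − trace(0)|` per cycle, with `t_es` predicted from
that cycle's own RR-derived heart rate. The 3D reduction projects the
displacement onto the main contraction direction — the normalised mean of
per-cycle unit vectors pointing from the cycle start to the farthest
excursion — estimated from the subject's *baseline* cycles per method, as
a monitoring system would do.

### Detection statistics

Per-cycle ESM values are repeated, correlated measurements within
subjects, so scores come from a random-intercept logistic model
(`logit P = b₀ + b₁·ESM + u_subject`). The fit is statsmodels'
`BinomialBayesMixedGLM.fit_vb` (mean-field variational Bayes): the
Laplace/MAP route diverged on our tables, while VB is stable and recovers
a generator intercept SD of 1.0 as ≈ 0.75. VB's default random starting
point is replaced with a deterministic one so repeated runs are
byte-identical. Fallbacks, each with a logged warning: plain logistic
regression when fewer than 3 subjects are present or the intercept SD
collapses to ~0, and a ridge-penalised fit under complete separation.

AUC is the Mann–Whitney estimator with ties counted ½ (identical to the
trapezoidal area under the tie-grouped ROC polygon). ROC operating points
use the rule `score ≥ threshold → positive` at every distinct score.
Paired curves are compared with DeLong's placement-value covariance test.
The positive class is ischemia with or without dobutamine; baseline,
dobutamine and reperfusion are negative.

One measured caveat: the model's fitted probabilities include the subject
intercepts, which absorb per-subject label imbalance *in-sample*. Under
the null (labels permuted, independent of ESM) the fixed-effect component
scores at chance (AUC 0.50–0.53 across seeds), but the full fitted
probabilities inflate to ≈ 0.56–0.62 depending on the subjects-per-row
ratio. In-sample AUCs from this route are therefore slightly optimistic
near the null; conclusions here rest on comparisons between methods on the
same rows, which share the inflation.

### Spectral analysis

Welch periodogram: 600-sample Hann windows, 595-sample overlap, segments
zero-padded to 8192 points (bin width 700/8192 ≈ 0.085 Hz — the raw
600-sample bin of ≈ 1.17 Hz cannot place a ~2 Hz heart-rate fundamental),
constant detrend, power normalised to sum to one. The dominant frequency
is the global maximum, ties resolving to the lowest frequency. The short
window (~1.5 cardiac cycles at 108 bpm) smears the fundamental by about
one padded bin; dominant-frequency statements are therefore made at
±0.1 Hz, not one bin.

## Numerical conventions

- Sampling: cycle length is `round(fs·60/HR)` samples; ground-truth peak
  values are exact analytically but sampled quantities can differ from
  them by up to one sample's worth of slope.
- The ECG is a 10-sample triangular spike per cycle (apex 5 samples after
  the cycle start). Simulated recordings carry ground-truth R-peak
  indices; the detector (median + 8·MAD adaptive threshold with a
  refractory period) is exact on clean spike trains and is used when no
  peaks are supplied.
- CSV output uses 17 significant digits, so float64 values round-trip
  exactly through text; `.npz` output is bit-exact by construction.
- All pipeline outputs are deterministic for a fixed seed (JSON keys
  sorted, fixed float formatting): re-running a config reproduces
  byte-identical files.

## Limitations

- The simulator is a rigid single-segment model: rotation and translation
  share one waveform family and are exactly in phase, tissue deformation
  is collapsed into one segment-length trace, and the sensor is noise-free
  apart from white noise and a constant gyro bias. Real epicardial signals
  contain respiration, baseline wander and sensor misalignment that are
  not modelled.
- The end-systole regression is treated as exact; the residual
  spread (tens of ms) is not propagated into the simulated timing.
- Rotation is modelled about a single fixed axis; out-of-plane rotation
  components are zero, which favours the one-axis ROT metric.
- The default cohort saturates detection (AUC 1.0 for every method), so
  method *ordering* at the default scale is degenerate; graded comparisons
  require raising the biological variability, as done in the examples.
- Group-level calibration targets are means; the simulator reproduces them
  as medians of noiseless recordings, and cohort draws match the reference
  between-subject SDs only in distribution.
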