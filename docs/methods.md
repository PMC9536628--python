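# Methods

## Signal model and preprocessing

A trunk-worn IMU at the L3–L4 level samples tri-axial acceleration
(±8 g) and angular velocity (±1000 °/s) at 250 Hz. Internally all
accelerations are in g (converted to cm/s² only inside integration),
angles in degrees, time in seconds.

**Re-orientation.** The sensor frame is rotated into a gait frame
(x forward, y lateral, z up) in two steps: the mean acceleration over a
window (default: the whole recording, which over whole strides of steady
walking averages to gravity) defines the vertical; the first principal
direction of the residual horizontal acceleration defines the forward
axis, signed so that the mean forward jerk at vertical-acceleration
peaks is positive. The same rotation is applied to the gyroscope, so the
transform is an isometry of both signals. A mean acceleration below
0.2 g (free-fall-like) is an unrecoverable orientation and an error.

**Smoothing.** A zero-phase Hann-weighted moving average, default window
25 samples (0.1 s at 250 Hz). The window passes the step-frequency band
(≤ 3 Hz; attenuation at 2 Hz ≈ 2.4%) while suppressing broadband sensor
noise; edges are reflect-padded to avoid amplitude bias at walk
boundaries. A window of 1 is the identity; even or non-positive windows
are rejected.

**Step detection.** Peaks of the smoothed vertical acceleration with
default prominence 0.05 g and minimum separation 0.3 s (cadence ceiling
200 steps/min). A flat signal yields zero steps, which is a valid
result, not an error.

**Side assignment.** The integrated, linearly detrended yaw angle is
sampled at each step; a strictly alternating sign pattern with all
|yaw| ≥ 0.1° assigns left/right (positive yaw → left by convention).
Any tie or broken alternation leaves every side `unknown` — degenerate
yaw carries no lateralizing information.

**Steady-state trimming.** Without position data, the acceleration and
deceleration phases at the walkway ends are approximated by dropping
k = 2 steps at each end (2 m at a typical older-adult step length of
≈ 0.6 m), configurable as a step count or a time margin. Fewer than four
retained steps is an insufficient walk.

**Gaps.** Up to 5 consecutive missing samples are linearly interpolated
onto the uniform grid; longer gaps are a hard data error, as double
integration across them is unreliable.

## Gait features

* **Cadence** = 60 (n−1)/(t_last − t_first) over the retained steps.
* **VHD** — per step interval: subtract the interval-mean vertical
  acceleration (gravity + bias), integrate twice with trapezoids,
  re-zero the mean velocity, remove the line through the position
  endpoints, and take max − min; the mean over steps, in cm. The
  construction is exactly invariant to constant acceleration offsets and
  linear-in-time velocity drift. Integration uses the *smoothed*
  vertical acceleration: the ≈2% amplitude cost at 2 Hz is far smaller
  than the noise amplification double integration would otherwise
  suffer.
* **Roll / yaw excursions** — integrate the forward-axis and
  vertical-axis angular velocities to angles; per stride, remove the
  endpoint line and take max − min; average across strides. Constant
  gyro bias integrates to a ramp and cancels exactly.

Two quantities here were genuinely open design choices:

* *Displacement vs midpoint reading of VHD.* VHD is implemented as the
  **difference** between the maximum and minimum vertical height within
  a step. The alternative "mean of the maximum and minimum heights" is
  not a displacement (it depends on the arbitrary position offset of an
  integrated signal) and is incompatible with typical printed values
  (≈3.3 cm) for older-adult CoM excursion.
* *Endpoint-line vs least-squares detrend.* A least-squares linear
  detrend of one full period of a sinusoid has a non-zero fitted slope
  (a sine is not orthogonal to a ramp over one period) and inflates the
  max − min excursion by ≈11%. The line through the segment endpoints
  removes offsets and integration ramps exactly while leaving
  whole-period oscillations untouched, so per-step and per-stride
  excursions are unbiased for periodic gait.

Strides join consecutive same-side steps when sides are known, otherwise
every second step — identical pairings under strict alternation.

## Speed models

Coefficients ship as versioned JSON assets (`model0.json`,
`model1.json`, `model2.json`) so refitted models are drop-in. All models
are affine; predictions are exactly linear in each predictor. Subgroup
routing for a new subject uses the model-1 speed: step length =
speed × 60 / cadence (cm), NSL = step length / height, nearest of the
three NSL centroids with ties to the lower subgroup. Routing is a
deterministic reproduction of how the subgroups were constructed, which
avoids requiring any refit at prediction time. An NSL outside the
centroid span widened by three within-subgroup SDs still yields a
prediction but sets an extrapolation flag.

## Model development pipeline

Ordinary least squares with a variance-inflation-factor screen:
VIF_j = 1/(1 − R²_j) from regressing predictor j on the rest; while any
VIF ≥ 2.5 the worst offender is dropped (iterative drop-worst — the
standard practice and guaranteed to reach a set satisfying the rule).
Reports carry unstandardized β with SE, standardized B, classical
t-distribution p-values, and VIF per retained feature.

The NSL clustering is solved **exactly** by dynamic programming over the
sorted values (1-D k-means optima are contiguous in sorted order), so
the pipeline is deterministic and globally optimal; the seed argument
exists only for API symmetry. Subgroup refits reuse the base model's
retained feature set without re-screening, and each subgroup must
contain at least p + 2 subjects.

One caution for recovery experiments: the pipeline assigns subgroups by
k-means on NSL derived from its *own* refit base model. On synthetic
cohorts this reshuffles a boundary fraction of subjects relative to the
generator's routing, and the resulting contamination of subgroup fits is
not captured by OLS standard errors. Tests therefore check subgroup
coefficient recovery under the generator's own labels, and structural
agreement (centroids, label overlap, in-sample RMSE) for the full
pipeline.

## Agreement metrics

Percent errors are relative to the reference (gold-standard) speed:
e_i = 100 (est_i − ref_i)/ref_i, ME = mean, MAE = mean absolute; RMSE in
cm/s. The ICC defaults to the two-way random, single-rater,
absolute-agreement form ICC(2,1) — device-versus-reference agreement is
an absolute question — with the consistency form ICC(3,1) available by
configuration; both come from the paired-table ANOVA mean squares (via
pingouin) with 95% CIs. Speed strata use mean ± 1 population SD of the
reference speeds with strict inequalities (slow below, fast above);
zero-spread samples are all medium. The evaluation table mirrors the
model × {slow, medium, fast, all} layout; empty strata produce n = 0
rows with null metrics.

## Synthetic data

The pendulum analytics follow the stance-phase spring-loaded inverted
pendulum: step length 2 l₁ β₁(0) sin a, normalized step length
2 α₁ β₁(0) sin a (α₁ the leg/height ratio), and conserved energy
½ m₁ l_l² ω₁² [1 − (l_s²/4l_l²)²], strictly decreasing in step length.
Only β₁(0) enters these expressions, so no stance-time profile of the
bending coefficient is modeled.

The walk simulator is **kinematic**, not a forward dynamic integration:
it prescribes a vertical CoM sinusoid at step frequency with
peak-to-peak equal to the commanded VHD, forward (0.05 g) and lateral
(0.03 g) acceleration oscillations that make the forward axis
identifiable, and stride-frequency roll/yaw sinusoids phased so the yaw
sign alternates across steps (the side ground truth). Trajectories are
differentiated to sensor signals, gravity added, Gaussian noise applied
(defaults 0.02 g and 1 °/s RMS — realistic trunk-MEMS levels, well above
the device resolution of 0.004 g / 0.03 °/s), and optionally a known
misalignment rotation. A frequency ramp option emulates gait initiation
for trimming tests. Commanded vertical oscillations above 0.5 g are
rejected as outside plausible gait. What the simulator deliberately does
*not* emulate: turning, asymmetric or pathological gait, step-to-step
timing variability, soft-tissue artifact, or sensor drift — so passing
round-trip tests demonstrates correctness of the signal chain on clean
periodic gait, not robustness to every clinical artifact.

Synthetic cohorts draw anthropometrics and features from truncated
normal marginals whose defaults are the reference cohort's published
means/SDs (whole-cohort or per NSL subgroup), independently by default —
no joint covariance is published — with a hook accepting a correlation
matrix. Reference speeds are the generator model's prediction plus
N(0, residual SD) noise, emulating the instrumented-walkway reading;
with a subgroup generator, membership is routed through the base model
exactly as at prediction time, and stored for recovery experiments.

## Problem sizes and numerical choices

Default test problem sizes — 12 s walks, cohorts of 1 500–10 000 — were
chosen so every stage's statistical checks are well powered while the
whole suite runs in seconds. Coefficient-recovery checks use max-|z|
bands calibrated to the number of simultaneous comparisons (2 SE for a
single 9-coefficient fit, 3.5 SE across 24 subgroup coefficients).
Rotations preserve vector norms to 1e-9 relative tolerance; OLS mean
recovery holds to machine precision; k-means ties and label order are
fixed by the sorted-contiguity construction. Degenerate inputs (constant
predictors, fewer distinct NSL values than clusters, zero-variance
agreement tables) raise typed errors at the first stage that can detect
them.

## Known limitations

Models are calibrated for healthy older adults walking straight at a
comfortable pace; accuracy degrades for frail or pathological gait, and
the package deliberately excludes turn detection, stair/slope walking,
real-time streaming and magnetometer fusion. The printed coefficients
are in-sample fits; no cross-validated generalization claim is made.
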