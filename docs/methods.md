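# Methods

## Conventions

All public angles are degrees and angular velocities °/s; internal
computation is in radians. Quaternions are scalar-first `(w, x, y, z)` and
represent world-from-sensor (or world-from-segment) rotations. The
anatomical frame is right-handed with **X anterior, Y to the subject's
left, Z up**; the world frame coincides with the (upright, forward-facing)
neutral pose at calibration. Euler decomposition is **intrinsic Z-Y-X**:
angle 1 is axial rotation about the vertical axis (transverse plane,
positive = leftward), angle 2 is flexion about the mediolateral axis
(sagittal plane, positive = anterior axis tipping down), angle 3 is lateral
bending. Nothing in the measured tasks identifies the convention the
original optical software used; Z-Y-X is a configuration constant here,
chosen so that the two planes the tasks exercise occupy the first two
(least cross-talk-prone) slots. Gimbal lock (|angle 2| ≥ 89.999°) is
flagged and angle 3 reported as 0; the tasks stay far from it.

## Orientation filter (IMU arm)

A multiplicative error-state Kalman filter with a 6-dimensional error state
(attitude error, gyro bias). Propagation uses midpoint (trapezoidal) gyro
samples, keeping quaternion integration second-order. Two corrections:

- **Gravity (tilt)** — vector measurement of the normalised accelerometer
  against the predicted world-up direction, applied only when ‖a‖ is within
  10% of 1 g **and** the gyro magnitude is below 15 °/s. The second gate
  matters: the forehead sensor sits ~12 cm from the axis of head rotation,
  so brisk turns produce centripetal/tangential accelerations that tilt the
  apparent gravity direction; uncorrected, those updates leak into the yaw
  and bias states.
- **Heading** — a scalar yaw update from the horizontal magnetometer
  component. Restricting the magnetometer to heading means magnetic
  disturbance can never corrupt tilt.

Defaults (`FusionParams`): gyro white noise 0.5 °/s, bias random walk
0.02 °/s·√s, gravity-direction noise 0.06 rad (deliberately inflated above
the sensor noise floor to tolerate motion acceleration), heading noise
0.05 rad, initial attitude from 0.5 s of averaged accelerometer +
magnetometer (TRIAD). These were calibrated once against the synthetic
generator's default noise model.

**Bias handling for metrics.** The filter estimates bias states, but during
vigorous motion transient attitude error partially aliases into them. The
pipeline therefore subtracts the *mean raw gyro over the static window*
(where the reading is exactly the bias) before projecting angular velocity;
the filter's per-sample estimate remains available.

**Static calibration.** The first ~3 s of every recording is a stationary
neutral pose. The mean orientation over a window inside it (Markley
quaternion average) gives the sensor-to-segment correction
`C = R̄ᵀ`, applied by right-multiplication so the neutral pose maps to
identity. The window must be ≥ 1 s and quiet (angular-velocity RMS < 3 °/s,
computed from the raw gyro when available, otherwise from smoothed
quaternion increments); violations raise `CalibrationError` naming the
offending statistic.

**Plane kinematics.** The bias-corrected gyro is rotated into the anatomical
frame (`ω_body = Cᵀ ω_sensor`) and projected on the plane normal (Z for
transverse, Y for sagittal). Peak velocity is read from this projected gyro
signal directly — the gyro is the primary measurement — rather than from
differentiated displacement. Displacement is the trapezoidal running
integral; ROM is computed per turn as `angle(end) − angle(start)`, which
bounds integration drift to a single half-cycle, so the optional
re-zeroing at velocity zero-crossings (`reset_at_zero_crossings`) is off by
default.

## Optical criterion arm

Processing order: gap-fill → filter → frames → resample → decompose →
differentiate.

- **Gap filling**: cubic spline per coordinate for gaps ≤ 0.5 s (interior
  only); longer gaps stay missing and are reported.
- **Filtering**: dual-pass (zero-phase) 2nd-order Butterworth, 6 Hz cutoff,
  per contiguous gap-free span; squared magnitude `1/(1+(f/6)⁴)`.
- **Segment frames**: mediolateral axis taken exactly (origin → right
  landmark), anterior-posterior orthogonalised against it, vertical
  = ML × AP. ML is primary because the left/right conditions are the
  protocol's primary movements. The forehead and sternum landmarks sit
  above/below their segment origins, so the raw triad is pitched; the
  static-pose correction is a constant *local-frame* rotation
  (`R(t) ← R(t) R̄ᵀ`, right-multiplied) that levels the AP axis — a
  left-side correction would conjugate yaw into roll by the tilt angle. A
  triad whose vertical axis points down in the static pose indicates
  swapped left/right labels and is rejected.
- **Resampling**: 120 → 128 Hz; quaternion slerp for rotations, cubic
  spline for scalar series and origins.
- **Angles/velocity**: Z-Y-X decomposition, unwrapped; central differences
  (one-sided at the ends).

Zero-phase filtering and differentiation both misbehave in the first/last
few tenths of a second of a record; segmentation never uses those edge
samples because partial leading/trailing spans are discarded.

## Turn segmentation and exclusion

**Head turns** are spans between zero-crossings of the plane velocity after
a 2 Hz zero-phase low-pass (crossing detection only — ROM and peak velocity
are read from the unsmoothed series). A crossing counts as a reversal only
if the smoothed velocity reaches ≥ 1 °/s on both sides (hysteresis), so
numerical wobble in quiet phases cannot fragment the series. Turns are
discarded when they overlap the exclusion mask, fall inside the static
calibration window (posture wobble around movement onset is not exercise),
have ROM < 5° or peak velocity < 10 °/s, or contain missing samples. For a
pure sinusoid of amplitude A this yields one turn per half-cycle with
ROM = 2A and peak velocity 2πfA exactly.

**Locomotor turns**: the walking task's 180° direction changes are detected
on the trunk transverse (heading) series. Because the voluntary left/right
oscillation (0.3–0.8 Hz) overlaps the path-turn band (~0.4 Hz), a
velocity-run detector cannot separate them; instead the unwrapped heading
is zero-phase low-passed at 0.3 Hz — averaging out the zero-mean
oscillation while keeping the 180° steps — and intervals whose trend slope
exceeds 10 °/s are flagged when net angle > 45° **and** peak raw velocity
> 15 °/s (the protocol's thresholds). The mask adds a 0.25 s guard band.
On synthetic trials this covers ≥ 95% (in practice 100%) of the true turn
samples at every tested oscillation frequency, flags nothing in standing
trials, and never flags a 30°/10 °/s sway.

## Agreement statistics

ICC(A,1) from the two-way ANOVA mean squares
`(MSR − MSE)/(MSR + (k−1)MSE + k(MSC − MSE)/n)` with k = 2 devices;
zero between-unit variance raises `UndefinedICCError` rather than returning
0, and negative values are reported with a warning, not clamped. RMSE is
√mean((IMU − mocap)²); percent error is the signed mean of
100·(IMU − mocap)/mocap (signed errors may cancel — that is the printed
convention); Bland-Altman limits are bias ± 1.96 × sample SD of the
differences. Koo–Li categories: < 0.5 poor, ≤ 0.75 moderate, ≤ 0.9 good,
else excellent (boundaries on the lower category). Condition summaries
append the column mean and sample SD (n−1) over the eight conditions;
display rounding is half-away-from-zero at each column's printed precision
while full precision is kept internally. The unit of analysis is the trial
(subjects × trials pooled per condition).

## Synthetic data generator

The generator defines the study conditions; its deterministic motion model
consumes no randomness, so specs differing only in seed share identical
ground truth.

- **Motion**: head oscillation A·sin(2πft) in the condition's plane with a
  one-cycle raised-cosine onset ramp (set `onset_ramp_cycles=0` for the
  literal pure sinusoid); defaults 45° peak-to-peak at 0.5 Hz — plausible
  vestibular-exercise pacing, *not* measurements of any cohort — with
  per-subject study draws of 30–60° and 0.4–0.8 Hz. Trunk coupling 1.0 in
  the en-bloc (VMS) tasks, 0.3 otherwise (people do not hold the trunk
  perfectly still). Walking adds a 3.9 m walkway traversed at 1.1 m/s
  (0.4 m/s tandem), raised-cosine 180° turns of 2.5 s at the ends, vertical
  bounce and small (< 5°) pitch/roll sway at step frequency, with the head
  transmitting half the sway. Every trial starts with a 3 s stationary
  neutral lead-in.
- **IMU synthesis**: exact body angular velocity from the Euler rates,
  rotated through the (optional) constant mounting misalignment, plus a
  constant bias vector (default magnitude 0.5 °/s, random direction) and
  white noise (0.5 °/s); accelerometer = specific force at the mounting
  point (gravity + linear acceleration of the moving, bouncing segment) +
  noise; magnetometer = Earth field (0.2 gauss horizontal, −0.4 vertical)
  in the sensor frame + noise. Channels clip at the advertised ranges
  (±6 g, ±2000 °/s, ±6 gauss) with a saturation warning.
- **Markers**: six markers at fixed segment-local offsets moved rigidly by
  the true rotations, plus low-frequency (≲1.5 Hz) soft-tissue artifact
  (SD 1.5 mm) and, in walking trials, 0.35 s occlusion dropouts centred in
  each path turn.

What the generator does **not** emulate: physiological gait detail, symptom
-driven movement avoidance, magnetic field distortion (hook available,
off by default), camera-volume-dependent optical accuracy, or clock offset
between the 120 Hz and 128 Hz streams (hardware-synchronised in the
emulated setup; configurable). Passing tests therefore demonstrate
correctness of the algorithms under this error model, not device
performance on human data.

**Ground truth for recovery checks** is the turn-wise summary of the true
(noise-free) angle series under the same segmentation rule. In walking
trials the true series legitimately contains gait sway, so this — not the
bare 2A closed form — is the estimation target; for standing pure
sinusoids the two coincide exactly.

## Numerical choices

- EKF inner loop uses scalar quaternion arithmetic and closed-form 3×3
  inversion (≈20k steps/s in pure Python; a 33 s two-sensor trial fuses in
  ≈0.4 s).
- Quaternion means use Markley's eigenvector method; hemisphere continuity
  is enforced on output series.
- Spline gap-filling is exact on polynomials ≤ 3; resampling error for
  3 Hz-band-limited signals is < 0.1% RMS.
- Default problem sizes: 30 s trials + 3 s lead-in; the bundled synthetic
  study uses 10 subjects × 2 trials × 8 conditions (160 trials), matching
  the emulated protocol, and completes in under a minute.

## Known limitations

- Joint (head-on-trunk) angles are out of scope; both arms report segment
  angles in the world/neutral frame.
- The magnetometer is required; there is no magnetometer-free mode, and
  indoor magnetic distortion is not modelled by default.
- Percent error uses trial-level averages (turn-level aggregation is a
  one-line change but is not the default).
- The heading-trend turn detector assumes path turns are rarer than ~one
  per 3 s; back-to-back pivot turns would merge into one exclusion
  interval (harmless for exclusion purposes).
- Published summary tables can be reproduced from their printed
  per-condition cells for the mean rows; some printed SD cells are only
  consistent with unrounded source values and cannot be matched exactly
  from the printed inputs.
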