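# vestkin

Head and trunk movement metrics from wearable inertial measurement units
(IMUs), with an optical motion-capture criterion pipeline and the
method-agreement statistics used to validate one against the other.

## The problem

Vestibular rehabilitation after concussion prescribes repeated head turns —
left/right (transverse plane) and up/down (sagittal plane) — while standing
and walking. Clinicians want two numbers per exercise bout: the average
**range of motion** (ROM, degrees per head turn) and the average **peak
rotational velocity** (ω_p, °/s per head turn). Optical motion capture can
measure both but is confined to a laboratory; a forehead IMU and a sternum
IMU are cheap and wearable, *if* their output can be trusted. This package
implements both measurement chains and the agreement protocol that compares
them:

- **IMU arm** — quaternion orientation by a multiplicative error-state
  Kalman filter (gyro propagation, accelerometer tilt correction gated on
  ‖a‖ ≈ 1 g, magnetometer heading-only correction, gyro-bias states);
  sensor-to-segment alignment from a ~3 s static neutral pose; angular
  velocity projected onto the anatomical plane of interest; trapezoidal
  integration to angular displacement.
- **Motion-capture arm** — six markers (forehead, bilateral mandibular
  condyles, sternum, bilateral acromions) → cubic-spline gap filling →
  dual-pass 2nd-order Butterworth low-pass (6 Hz) → right-handed anatomical
  segment frames (mediolateral axis exact, anterior-posterior orthogonalised,
  vertical completing the triad; static-pose correction levels the AP axis)
  → up-sampling 120 → 128 Hz → intrinsic Z-Y-X Euler decomposition →
  central-difference velocity.
- **Segmentation** — each trial is cut into individual head turns at
  velocity zero-crossings (2 Hz smoothed for crossing detection, with a
  small hysteresis); in walking trials the 180° turns at the walkway ends
  are detected on the trunk heading (net angle > 45° **and** peak velocity
  > 15 °/s) and excluded with a 0.25 s guard band.
- **Agreement** — ICC(A,1) (two-way random effects, absolute agreement,
  single measure), RMSE, signed percent error, Bland-Altman bias and
  ±1.96 SD limits, Koo–Li interpretation, and mean/SD summary rows across
  the eight task conditions.
- **Synthetic data** — no human recordings ship with the package; a
  generator produces paired IMU + marker streams with analytic ground truth
  for every condition (sinusoidal head oscillation, en-bloc trunk coupling,
  gait bounce/sway, 180° path turns, gyro bias and noise, soft-tissue
  artifact, marker occlusion at turns, mounting misalignment), so the whole
  chain is testable end to end.

## Worked example

```python
import numpy as np
from vestkin import (SyntheticTrialSpec, generate_trial,
                     imu_arm_metrics, mocap_arm_metrics, RunConfig)

spec = SyntheticTrialSpec(condition="walk_LR", head_rom_true=45.0,
                          oscillation_freq=0.5, seed=3)
head, trunk, markers, truth = generate_trial(spec)
cfg = RunConfig()
imu = imu_arm_metrics(head, trunk, "walk_LR", cfg)["head"]
moc = mocap_arm_metrics(markers, "walk_LR", cfg)["head"]
print(f"IMU   : ROM {imu.avg_rom:.2f} deg, peak {imu.avg_peak_velocity:.2f} deg/s, n={imu.n_turns}")
print(f"Mocap : ROM {moc.avg_rom:.2f} deg, peak {moc.avg_peak_velocity:.2f} deg/s, n={moc.n_turns}")
```

prints

```
IMU   : ROM 42.40 deg, peak 68.63 deg/s, n=9
Mocap : ROM 42.27 deg, peak 71.60 deg/s, n=9
```

— nine accepted head turns on the straight walkway segments (the four 180°
path turns are excluded, and turns ramping up right after movement onset
fall below the full 45° amplitude), with the wearable and optical estimates
of average turn amplitude within 0.2° and of peak turning speed within
~3 °/s of each other under the generator's default sensor noise and
soft-tissue artifact — the size of disagreement the ICC/RMSE protocol is
there to quantify.

A full study runs from the shell:

```bash
vestkin simulate --out study/ --subjects 10 --trials 2 --seed 1
vestkin validate --manifest study/manifest.csv --out study/results/
```

writing per-trial metrics, per-condition ICC/RMSE/%error tables with
mean/SD-across-conditions rows, and Bland-Altman coordinates as CSV.

## Layout

| module | contents |
| --- | --- |
| `vestkin.rotations` | quaternions, rotation matrices, intrinsic Z-Y-X Euler, frame alignment |
| `vestkin.streams` | `ImuStream`, `MarkerStream`, `OrientationSeries`, `PlaneAngleSeries` |
| `vestkin.simulate` | synthetic trial/study generator with analytic ground truth |
| `vestkin.imu` | Kalman sensor fusion, static calibration, plane velocity, integration |
| `vestkin.mocap` | gap filling, filtering, segment frames, resampling, Euler, differentiation |
| `vestkin.turns` | head-turn segmentation, locomotor-turn exclusion, trial metrics |
| `vestkin.agreement` | ICC(A,1), RMSE, percent error, Bland-Altman, condition summaries |
| `vestkin.fileio`, `vestkin.pipeline`, `vestkin.cli` | file formats, end-to-end runs, command line |

See `docs/methods.md` for the model conventions, parameter defaults and
known limitations.
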