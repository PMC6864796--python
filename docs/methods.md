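# Methods

This note documents the models, the tunable parameters, the synthetic-data
generator and the design choices behind `gaitfes`, with the reasoning a
maintainer needs to re-derive or change them.

## Signal model and frames

A foot-mounted 6-axis IMU measures specific force (m/s²) and angular
velocity (°/s) in its own case frame at a nominal 500 Hz. The *foot frame*
has x forward, y along the pitch axis (pointing left), z up; at rest the
accelerometer reads the gravity reaction (0, 0, +9.81) m/s². Degrees per
second are used throughout — the sensor range (±2000 °/s) and all
thresholds share the scale, so no unit conversions occur inside the
pipeline. Timestamps are seconds from stream start; sample indexing is
0-based.

A stream must have strictly increasing timestamps whose **median** spacing
matches the declared rate within 1%. Individual gaps are tolerated on
purpose: dropped samples (lost radio link) are a first-class error mode,
handled downstream by invalidating the gait cycles that span a gap larger
than `max_gap_s` (default 0.05 s) rather than by rejecting the file.

## Alignment

The mounting rotation is estimated from Full Contact (gyro quiescence) and
heel-rise rotation; see the README for the construction. Numerical and
design choices:

* **Gravity averaging.** The foot-z axis is the mean accelerometer vector
  over the whole `k_fc` quiescence window, not a single sample: a
  one-sample gravity estimate at 0.2 m/s² sensor noise would tilt ẑ by
  ~1°, while the 50-sample mean reduces this ~7-fold.
* **Signed vs absolute gyro sums.** The per-axis *absolute* sums identify
  the main rotation axis, but as a vector they are wrong whenever the true
  pitch axis has mixed-sign components in the sensor frame (taking
  |·| componentwise folds the vector into the positive octant). The
  rotation matrix is therefore built from the *signed* sums, whose
  direction is exact up to an overall sign; the sign is then fixed so
  heel-rise pitch rate is positive in the foot frame, which the Toe-Off
  conditions assume.
* **Re-orthogonalization.** x̂ = ŷ_raw × ẑ_raw is perpendicular to ẑ but
  ŷ_raw is generally not; ŷ is recomputed as ẑ × x̂ so R is a proper
  rotation (R Rᵀ = I, det = +1, enforced at 1e-9). Without this the
  rotated frame would be sheared.
* **Sign of ẑ.** ẑ points along the measured gravity reaction, so rotated
  resting acceleration is **+9.81 m/s²**. (Resting-phase statistics of
  rotated recordings in this setting report ≈ +9.9 to +10.0 m/s²,
  confirming the positive convention.)
* **Degenerate streams.** A resting stream has no rotation to define ŷ.
  If the largest |signed sum| is below `2·ω_thresh·√n` (what
  quiescence-band noise could plausibly accumulate) the estimate is
  flagged `degenerate` and an arbitrary axis perpendicular to gravity is
  used — gravity restoration still works exactly, only yaw is undefined.
  The offline `align_stream` substitutes the nearest non-degenerate
  estimate when one exists; the streaming detector cannot look ahead and
  keeps the degenerate one until a better estimate completes.

Parameters (all exposed in `AlignmentConfig`; none are printed device
constants):

| parameter | default | why |
|---|---|---|
| `omega_fullcontact_thresh` | 20 °/s | well above sensor noise (~1 °/s), well below heel-rise rates (>40 °/s) |
| `k_fc` | 50 samples (0.1 s) | fits inside the shortest foot-flat phase at the fastest training speed |
| `k_y` | 325 samples (0.65 s) | must reach past heel rise at the slowest cycle (1.4 s) yet end before the swing reversal at the fastest (1.05 s), where the signed sums would cancel |

## Detection

* **Jerk** is a first-order backward difference of foot-frame a_z scaled
  by the sampling rate — causal, so streaming-compatible. When the
  rotation matrix refreshes, the previous sample is re-rotated under the
  *new* matrix before differencing, so a matrix update can never
  manufacture a jerk spike. An optional trailing moving average
  (`jerk_smooth_width`, default off) trades peak amplitude for noise
  rejection.
* **Floating IC band**: exponential blend `thr' = (1−α)·thr + α·γ·peak`
  with α = 0.3, γ = (0.5, 1.5). The blend keeps the previous threshold in
  play and adds a percentage of the current jerk; a single outlier step
  moves the band by at most 30% of the way. The "current peak" is the
  running max of |jerk| for 50 ms after the IC fires, because the detector
  fires on the rising edge, before the true peak.
* **Heel Off comparators.** The event is an *onset of rotation before
  translation*: |ω_y| must **exceed** its threshold while the three
  accelerations stay **below** theirs (a_z gravity-corrected, assuming a
  flat training surface). An all-below reading of the four conditions
  would fire trivially during foot flat and reduce Heel Off to a timer;
  both comparator directions are nevertheless config switches
  (`heeloff_omega_exceeds`, `heeloff_acc_below`) because the intended
  directions are a judgment call.
* **Toe Off** fires at the low-threshold crossing *after* the swing peak —
  the three conditions are sequential by definition — so the detected TO
  lags the kinematic toe-off. Downstream timing uses cycle percentages
  anchored on events, so a consistent lag is calibrated away by the anchor
  percentages.
* **Adaptation**: `f = clamp(ω_max/ω_ref, 0.5, 2)` with ω_ref = 300 °/s;
  ω_high/ω_low scale by f, the swing and roll gates by 1/f. Linear scaling
  is the simplest monotone rule; the clamp keeps one pathological swing
  from freezing the detector.
* **Full Contact event vs re-estimation.** Gyro quiescence can begin in
  the previous cycle's terminal swing and run through the heel strike
  (the IC pulse lives in the accelerometer only). The FSM's FC event
  therefore fires at the first *awaiting* sample where the run length is
  ≥ `k_fc`, while rotation re-estimation triggers once per quiescent
  stretch. A one-shot FC at exactly run == k_fc would skip the first
  cycle whenever rest merges into it.

Profile presets (`DetectorConfig.for_profile`): `lokomat` — jerk band
(500, 6000) m/s³, swing gate 0.25 s, no IC band; `lyra` — jerk band
(200, 3000) m/s³ (the end-effector trainer produces much lower
heel-strike jerk), swing gate 0.10 s, IC angular-velocity band
[−30, +30] °/s enabled. The lyra spike artifacts arrive late in swing,
after any plausible swing gate, which is why the band — not the gate — is
the effective defense. All numbers are package defaults to be calibrated
per installation, not device constants.

## Stimulation scheduling

Anchor percentages default to IC = 0, FC = 8, HO = 40, TO = 60 — standard
gait-phase positions of these events; they are config values.
`phase_percent`/`percent_to_time` interpolate piecewise-linearly through
the anchors of a cycle. The schedule builder is causal: switching times
inside cycle *k* are predicted from cycle *k−1*'s IC-to-IC duration, so
the first cycle (and any cycle whose predecessor is missing or invalid)
produces no stimulation. Wrap-around chart entries (start > stop, e.g.
90 → 16) produce intervals crossing the cycle boundary with on-fraction
((stop − start) mod 100)/100. Each chart entry binds to cycles of its own
side — the left and right charts are half-cycle-shifted copies, and each
limb's events come from its own sensor, so tying a chart row to the
contralateral cycle would double the timing error of any asymmetry.
Per-channel intervals are clipped to be non-overlapping. Actual pulse
delivery is out of scope; the schedule is the data product.

## Synthetic data generator

The generator emulates robot-induced foot motion in the foot frame and
then disguises it: pitch angle θ(t) is a piecewise smoothstep profile
(flat 0–40% of the cycle; heel rise to 10° over 40–60%; fast swing
rotation whose rate peaks at `swing_peak_omega` = 300 °/s just after the
60% toe-off mark; hold; re-levelling back to 0° over 74–96%), ω_y is its
exact analytic derivative, and the accelerometer reads gravity resolved
through θ plus a raised-cosine heel-strike pulse whose **peak jerk** is
the configured `ic_jerk_amp` (3000 m/s³ lokomat, 1200 lyra). A
terminating heel strike closes the last cycle. The stream is mapped
through the mounting rotation, Gaussian noise is added
(defaults 0.2 m/s², 1 °/s — the order of resting-phase scatter observed
on real foot-mounted sensors), and values are clipped to the sensor
ranges (never reached at default amplitudes). Everything derives from one
seeded generator; same seed, same bits.

Speed mapping: belt speeds 1.2/1.5/1.7 m/s → cycle durations
1.4/1.2/1.05 s (an editable table; the training literature quotes belt
speeds, not cadences).

What the generator does **not** emulate — and hence what passing tests do
not show: soft-tissue and strap resonances, robot-specific harmonic
content, baseline drift and temperature effects, asymmetric or
pathological gait, cross-axis coupling of the heel-strike transient, and
the detailed Lokomat/Lyra amplitude spectra. Detection rates of 100% on
clean synthetic signals establish internal consistency of detector and
signal model, not clinical performance; published detection rates on real
treadmill recordings (~94–98% with small type-1 errors) remain the
realistic expectation, and those recordings are not reproducible here.

Ground-truth FC/HO/TO timestamps mark where the underlying signal feature
*starts*; the detected FC lags by the quiescence run and TO fires after
the swing peak by construction, so step scoring anchors on Initial
Contacts (tolerance: 10% of the median reference cycle duration) and
timing accuracy is asserted tightly for ICs only.

## Evaluation

Normalization subtracts the mean and divides by the square root of the
autocorrelation maximum (= the energy of the centered signal), pinning
the autocorrelation maximum at exactly 1; it is idempotent and
scale-invariant, and a constant signal is rejected as degenerate.
Cross-similarity is the maximum cross-correlation of two normalized
signals over lags within ± half the shorter signal (configurable) —
bounded by 1 via Cauchy–Schwarz. Step matching is greedy one-to-one in
time order, which on sorted 1-D events with a fixed tolerance attains the
maximum matching (verified against an exhaustive oracle in the tests).
Windowed evaluation uses 75,000-sample windows (2.5 min at 500 Hz),
each snapped to start at a gyro-quiescent (rest) sample; per-window
detection rate and type-1/type-2 errors are reported with mean ± sd
across windows.

## Problem sizes used in the test suite

Simulated runs are desk-scale by choice: 10–20 cycles per stream for
completeness checks, 6 cycles × 50 random mountings for rotation
recovery, 1,000 disturbed 3-cycle runs for FSM safety, 150 s of rest for
the window-size check. These sizes exercise every code path (including
dropout recovery and threshold adaptation) while keeping the whole suite
under a minute of simulation time; nothing in the method scales
nonlinearly with stream length.

## Known limitations

* The detector assumes sagittal-plane, cyclic, robot-induced motion; it
  is not a general-purpose human-gait analyzer (no roll/yaw analysis, no
  cadence-free walking).
* Initial (pre-floating, pre-adaptation) thresholds are calibration
  parameters; no published values exist for either robot, so the defaults
  are tuned to the synthetic amplitudes and must be re-calibrated on real
  hardware.
* Yaw is unobservable during pure rest; the first rotation estimate of a
  session is yaw-arbitrary until the first gait cycle completes, and the
  first cycle under an adversarial mounting may be lost.
* Streams are processed per limb with no cross-leg plausibility checks.
* Bluetooth acquisition, clock synchronization and stimulator control are
  hardware concerns outside the package.
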