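# gaitfes

IMU-based gait-event detection and functional-electrical-stimulation (FES)
trigger scheduling for robot-assisted gait training.

Robot gait trainers (exoskeletons such as the Lokomat, end-effector systems
such as the Lyra) move a patient's legs through a cyclic gait pattern but
provide only passive motion; FES can activate the paretic muscles at the
right moments of the cycle, turning the combination into a hybrid
rehabilitation system. The missing link is knowing *where in the gait cycle
each foot is* — independently of the robot's internals, from a single
6-axis IMU (±16 g accelerometer, ±2000 °/s gyroscope, 500 Hz) strapped to
each foot in **any orientation**. This package implements that link for
engineers and researchers building such hybrid setups, plus the synthetic
signal generator and the scoring machinery needed to test it without access
to clinical recordings.

## The method

**Arbitrary sensor alignment.** The unknown mounting rotation between
sensor and foot axes is estimated from the signal itself and refreshed at
every midstance. During *Full Contact* (foot flat) all gyro components stay
inside a quiescence band for `k_fc` consecutive samples; the
window-averaged accelerometer vector there is the gravity reaction and
gives the foot ẑ. The heel rise after midstance rotates the foot about its
pitch axis, so the per-axis gyro sums over a window after Full Contact give
the pitch axis ŷ (the largest absolute sum identifies the main rotation
axis — no prior knowledge of the mounting needed). Then

```
x̂ = ŷ × ẑ,    R = [x̂; ŷ; ẑ]   (rows re-orthogonalized, det R = +1)
```

and every incoming sample is rotated into the foot frame:
ω_rot = R ω,  a_rot = R a. Signs are fixed so resting a_z ≈ +9.81 m/s² and
heel-rise pitch rate is positive.

**Event detection (finite-state machine).** Per limb, events must follow
IC → FC → HO → TO; anything out of sequence is discarded.

* *Initial Contact*: `jerk_min < |d a_z/dt| < jerk_max`, a **floating**
  band re-blended after every step from the previous band and a fraction of
  the current peak jerk (`thr' = (1−α)·thr + α·γ·peak`);
* *Full Contact*: the alignment quiescence condition;
* *Heel Off*: |ω_y| exceeds its threshold while |a_x|, |a_y|, |a_z − g|
  stay below theirs;
* *Toe Off*: sequentially ω_y > ω_high, then strictly decreasing for
  `k_to` samples, then ω_y < ω_low (the event fires there).

Temporal gates (minimum swing time before an IC, minimum roll time before a
HO) and the FSM intercept spikes, outliers and missing data; cycles that
span a sampling gap are marked invalid. The peak swing pitch rate of each
step rescales the TO thresholds (×f) and the gates (×1/f),
`f = clamp(ω_max/ω_ref, 0.5, 2)`, so the detector tracks treadmill speed.
A `lyra` device profile lowers the jerk band and adds an angular-velocity
band that rejects IC candidates while the foot is still rotating — the
end-effector trainer produces spurious jerk spikes during swing.

**Stimulation scheduling.** Each detected IC-to-IC cycle anchors known
cycle percentages (IC 0%, FC 8%, HO 40%, TO 60%, next IC 100%). An
eight-channel timing chart (quadriceps, biceps femoris, tibialis anterior,
gastrocnemius × both sides) switches each muscle on/off at fixed
percentages, predicted causally from the previous cycle's duration;
invalid cycles never stimulate. Stimulator settings are validated against
the 8-channel device limits (≤130 mA step 5 mA, 10–50 Hz step 5 Hz,
20–500 µs step 10 µs, biphasic rectangular).

**Scoring.** Detected steps are matched one-to-one to reference ICs within
a tolerance over 75,000-sample windows (2.5 min at 500 Hz):

```
detection rate = 100/N_ref · (N_det − N_inc),   type-1 error = 100/N_ref · N_inc
```

Type-1 (incorrect) detections are hazardous — they can mistime
stimulation; missed steps are not. Alignment quality is verified by
offset-removing and energy-normalizing the pitch-rate traces (so each
signal's autocorrelation maximum is exactly 1) and taking the maximum
cross-correlation between reference and rotated signal.

## Worked example

```
$ gaitfes simulate --seed 42 --out-stream stream.csv --out-truth truth.csv
wrote 13250 samples to stream.csv, 80 events to truth.csv
$ gaitfes detect --stream stream.csv --out-events events.csv --out-cycles cycles.csv
82 events, 20/20 valid cycles
$ gaitfes evaluate --stream stream.csv --detected events.csv --reference truth.csv --window-samples 5000
window 0: ref=8 det=8 rate=100.0% type1=0.0%
window 1: ref=8 det=8 rate=100.0% type1=0.0%
detection rate 100.0 ± 0.0 / type-1 0.0 ± 0.0
$ gaitfes schedule --stream stream.csv --out schedule.csv
4 channels, 76 intervals -> schedule.csv
```

The simulated recording holds 20 gait cycles (80 ground-truth events: one
IC, FC, HO, TO per cycle) with default sensor noise. The detector closes
all 20 cycles as valid; the 82 accepted events are the 20×4 cycle events
plus the opening of the next, unfinished cycle. Both 10-second evaluation
windows score a 100% detection rate with 0% type-1 error. The schedule
activates the four left-side chart channels (the stream is a left-foot
sensor) with one on/off interval per cycle that has a predecessor, e.g.
left biceps femoris on at 80% of each cycle for 32% of a cycle.

The same run with `--profile lyra` and `spurious_spike_rate: 2` in the
config demonstrates the angular-velocity band: with the band the spikes
are discarded, without it most cycles are detected at the wrong time
(see `tests/test_acceptance.py` and `tests/test_simulator.py`).

## Layout

```
src/gaitfes/
  imu_io.py       stream/event containers + CSV I/O
  alignment.py    sensor-to-foot rotation estimation
  detection.py    FSM event detector, floating thresholds, adaptation
  stimulation.py  timing chart, phase interpolation, FES schedules
  simulator.py    synthetic gait-signal generator with ground truth
  evaluation.py   step matching, detection rate/type-1, normalization
  cli.py          simulate / detect / evaluate / schedule commands
docs/methods.md   models, parameters, design choices, limitations
```
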