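"""Synthetic foot-IMU gait signals with ground truth.

Robot-assisted gait trainers impose a cyclic, sagittal-plane foot motion.
The generator reproduces the qualitative signal features the detector
keys on, cycle by cycle:

* a sharp one-sided **jerk pulse** in the foot-frame z acceleration at
  Initial Contact (the heel strike impact);
* a **quiet foot-flat interval** from Initial to Heel Off — gravity only,
  all gyro components near zero;
* a **heel-rise pitch rotation** starting at Heel Off;
* a **swing pitch-velocity peak** shortly after Toe Off, strictly
  decreasing after the peak, followed by a re-levelling counter-rotation
  that brings the foot back flat before the next Initial Contact.

The pitch angle is a piecewise-smoothstep profile; the pitch rate is its
exact analytic derivative and gravity is resolved into the instantaneous
foot orientation, so the angular velocity, the tilt and the acceleration
are mutually consistent.  The whole stream is then mapped into an
arbitrary sensor frame by a mounting rotation, noise is added, and the
values are clipped to the sensor ranges (±16 g, ±2000 °/s).

The lyra profile scales the heel-strike jerk down and injects spurious
jerk spikes while the foot is still rotating — the artifact pattern that
motivates the detector's IC angular-velocity band.

Shapes are bump/ramp primitives, not a biomechanical simulation: the
detector consumes only the features named above, and anything richer
would be unverifiable against desk-scale ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, field_validator
from scipy.spatial.transform import Rotation as ScipyRotation

from .imu_io import ACC_RANGE, GRAVITY, GYR_RANGE, EventKind, EventRecord, ImuStream

__all__ = [
    "GaitSimConfig",
    "GroundTruth",
    "simulate_gait",
    "apply_mounting",
    "inject_disturbance",
    "random_rotation",
    "SPEED_TO_CYCLE_DURATION",
]

#: Treadmill belt speed (m/s) -> gait cycle duration (s).  The rehab
#: literature gives belt speeds, not cadences; this editable table maps
#: the three standard training velocities onto plausible cycle durations.
SPEED_TO_CYCLE_DURATION = {1.2: 1.4, 1.5: 1.2, 1.7: 1.05}

# cycle-phase layout (fractions of the cycle duration)
_HO_START = 0.40   # heel rise begins
_SWING_START = 0.60  # fast swing rotation begins
_SWING_END = 0.72
_FALL_START = 0.74  # re-levelling counter-rotation
_FALL_END = 0.96
_THETA_HEEL = 10.0  # deg of heel-rise pitch
_IC_PULSE_S = 0.03  # duration of the heel-strike pulse

_PROFILE_JERK_AMP = {"lokomat": 3000.0, "lyra": 1200.0}
#: cycle phases at which lyra-style spurious jerk spikes are injected,
#: all during foot rotation (high |pitch rate|)
_SPIKE_PHASES = (0.85, 0.66, 0.78, 0.90)


class GaitSimConfig(BaseModel):
    """Study conditions for one synthetic recording."""

    model_config = ConfigDict(extra="forbid", arbitrary_types_allowed=True)

    fs: float = Field(default=500.0, gt=0)
    n_cycles: int = Field(default=20, ge=0)
    cycle_duration: float = Field(default=1.2, gt=0)
    rest_lead: float = Field(default=1.5, ge=0)
    rest_tail: float = Field(default=1.0, ge=0)
    profile: str = "lokomat"
    ic_jerk_amp: float | None = Field(default=None, gt=0)
    swing_peak_omega: float = Field(default=300.0, gt=0)
    event_pcts: tuple[float, float, float] = (8.0, 40.0, 60.0)
    #: None = identity; "random" = drawn from the seed; else a 3x3 proper rotation
    mounting_rotation: np.ndarray | str | None = None
    noise_sd_acc: float = Field(default=0.2, ge=0)
    noise_sd_gyr: float = Field(default=1.0, ge=0)
    spurious_spike_rate: float = Field(default=0.0, ge=0)
    dropout: tuple[float, float] | None = None
    side: str = "left"
    seed: int = 0

    @field_validator("event_pcts")
    @classmethod
    def _ordered(cls, v):
        fc, ho, to = v
        if not (0 < fc < ho < to < 100):
            raise ValueError("event percentages must satisfy 0 < FC < HO < TO < 100")
        return v

    @property
    def jerk_amp(self) -> float:
        if self.ic_jerk_amp is not None:
            return self.ic_jerk_amp
        return _PROFILE_JERK_AMP.get(self.profile, 3000.0)


@dataclass
class GroundTruth:
    """True event times, cycle spans and the mounting actually used."""

    events: list[EventRecord]
    cycle_spans: list[tuple[float, float]]
    mounting_rotation: np.ndarray
    foot_flat_intervals: list[tuple[float, float]]

    def times(self, kind: EventKind) -> np.ndarray:
        return np.array([e.t for e in self.events if e.kind == kind])


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """A proper rotation drawn uniformly from SO(3)."""
    return ScipyRotation.random(rng=rng).as_matrix()


def _smoothstep(x: np.ndarray) -> np.ndarray:
    x = np.clip(x, 0.0, 1.0)
    return 3 * x**2 - 2 * x**3


def _smoothstep_d(x: np.ndarray) -> np.ndarray:
    """Derivative of the smoothstep w.r.t. x (0 outside [0,1], peak 1.5)."""
    inside = (x >= 0) & (x <= 1)
    return np.where(inside, 6 * x - 6 * x**2, 0.0)


def _pitch_profile(u: np.ndarray, T: float, swing_peak_omega: float):
    """Pitch angle (deg) and pitch rate (deg/s) over cycle phase u in [0,1).

    Heel rise to ``_THETA_HEEL`` over [0.40, 0.60], fast swing rotation
    whose rate peaks at ``swing_peak_omega`` over [0.60, 0.72], hold, then
    re-levelling back to zero over [0.74, 0.96].  The rate is the exact
    analytic derivative of the angle.
    """
    theta_swing = swing_peak_omega * (_SWING_END - _SWING_START) * T / 1.5
    theta = np.zeros_like(u)
    omega = np.zeros_like(u)
    segs = [
        (_HO_START, _SWING_START, 0.0, _THETA_HEEL),
        (_SWING_START, _SWING_END, _THETA_HEEL, _THETA_HEEL + theta_swing),
        (_FALL_START, _FALL_END, _THETA_HEEL + theta_swing, 0.0),
    ]
    theta_max = _THETA_HEEL + theta_swing
    # hold at theta_max between swing end and fall start
    hold = (u >= _SWING_END) & (u < _FALL_START)
    theta[hold] = theta_max
    for lo, hi, a, b in segs:
        x = (u - lo) / (hi - lo)
        mask = (u >= lo) & (u < hi)
        theta[mask] = a + (b - a) * _smoothstep(x[mask])
        omega[mask] = (b - a) * _smoothstep_d(x[mask]) / ((hi - lo) * T)
    return theta, omega


def _raised_cosine_pulse(t: np.ndarray, t0: float, tau: float, amp_jerk: float) -> np.ndarray:
    """One-sided smooth acceleration pulse whose peak jerk is ``amp_jerk``."""
    x = (t - t0) / tau
    inside = (x >= 0) & (x < 1)
    pulse = np.zeros_like(t)
    # a(t) = A/2 (1 - cos(2π x)); da/dt peaks at A π / τ  => A = amp_jerk τ / π
    A = amp_jerk * tau / np.pi
    pulse[inside] = A / 2 * (1 - np.cos(2 * np.pi * x[inside]))
    return pulse


def simulate_gait(cfg: GaitSimConfig) -> tuple[ImuStream, GroundTruth]:
    """Generate one synthetic recording with ground truth.

    Deterministic given ``cfg.seed``: the mounting draw, the sensor noise
    and every disturbance come from one seeded generator.
    """
    rng = np.random.default_rng(cfg.seed)
    T = cfg.cycle_duration
    fs = cfg.fs
    total = cfg.rest_lead + cfg.n_cycles * T + cfg.rest_tail
    n = max(1, int(round(total * fs)))
    t = np.arange(n) / fs

    acc = np.zeros((n, 3))
    gyr = np.zeros((n, 3))
    theta_all = np.zeros(n)
    events: list[EventRecord] = []
    spans: list[tuple[float, float]] = []
    flats: list[tuple[float, float]] = []
    pct_fc, pct_ho, pct_to = cfg.event_pcts

    n_spikes = min(len(_SPIKE_PHASES), int(round(cfg.spurious_spike_rate)))

    for k in range(cfg.n_cycles):
        t0 = cfg.rest_lead + k * T
        spans.append((t0, t0 + T))
        flats.append((t0 + _IC_PULSE_S, t0 + _HO_START * T))
        u = (t - t0) / T
        in_cycle = (u >= 0) & (u < 1)
        th, om = _pitch_profile(np.where(in_cycle, u, 0.0), T, cfg.swing_peak_omega)
        theta_all[in_cycle] += th[in_cycle]
        gyr[in_cycle, 1] += om[in_cycle]
        acc[:, 2] += _raised_cosine_pulse(t, t0, _IC_PULSE_S, cfg.jerk_amp)
        for phase in _SPIKE_PHASES[:n_spikes]:
            acc[:, 2] += _raised_cosine_pulse(t, t0 + phase * T, _IC_PULSE_S, cfg.jerk_amp)
        for kind, pct in [(EventKind.IC, 0.0), (EventKind.FC, pct_fc),
                          (EventKind.HO, pct_ho), (EventKind.TO, pct_to)]:
            te = t0 + pct / 100.0 * T
            events.append(EventRecord(kind=kind, side=cfg.side,
                                      index=int(round(te * fs)), t=te))

    # terminating heel strike: the closing IC of the last cycle, so the
    # detector can close exactly n_cycles IC-to-IC cycles (not in the
    # ground-truth event list — its own cycle is not simulated)
    if cfg.n_cycles > 0:
        acc[:, 2] += _raised_cosine_pulse(
            t, cfg.rest_lead + cfg.n_cycles * T, _IC_PULSE_S, cfg.jerk_amp
        )

    # gravity resolved into the instantaneous foot orientation
    th_rad = np.deg2rad(theta_all)
    acc[:, 0] += -GRAVITY * np.sin(th_rad)
    acc[:, 2] += GRAVITY * np.cos(th_rad)

    if isinstance(cfg.mounting_rotation, str):
        if cfg.mounting_rotation != "random":
            raise ValueError("mounting_rotation must be None, 'random', or a 3x3 matrix")
        R0 = random_rotation(rng)
    elif cfg.mounting_rotation is None:
        R0 = np.eye(3)
    else:
        R0 = np.asarray(cfg.mounting_rotation, dtype=float)
    acc = acc @ R0.T
    gyr = gyr @ R0.T

    if cfg.noise_sd_acc > 0:
        acc = acc + rng.normal(0.0, cfg.noise_sd_acc, acc.shape)
    if cfg.noise_sd_gyr > 0:
        gyr = gyr + rng.normal(0.0, cfg.noise_sd_gyr, gyr.shape)
    acc = np.clip(acc, -ACC_RANGE, ACC_RANGE)
    gyr = np.clip(gyr, -GYR_RANGE, GYR_RANGE)

    stream = ImuStream(t=t, acc=acc, gyr=gyr, fs=fs, side=cfg.side,
                       label=f"sim:{cfg.profile}")
    if cfg.dropout is not None:
        stream = inject_disturbance(stream, "dropout", start=cfg.dropout[0],
                                    duration=cfg.dropout[1])
    truth = GroundTruth(events=events, cycle_spans=spans, mounting_rotation=R0,
                        foot_flat_intervals=flats)
    return stream, truth


def apply_mounting(stream: ImuStream, R0: np.ndarray) -> ImuStream:
    """Express a foot-frame stream in an arbitrarily rotated sensor frame."""
    R0 = np.asarray(R0, dtype=float)
    if R0.shape != (3, 3) or not np.allclose(R0 @ R0.T, np.eye(3), atol=1e-9) \
            or not np.isclose(np.linalg.det(R0), 1.0, atol=1e-9):
        raise ValueError("mounting must be a proper 3x3 rotation")
    out = stream.copy()
    out.acc = stream.acc @ R0.T
    out.gyr = stream.gyr @ R0.T
    return out


def inject_disturbance(stream: ImuStream, kind: str, **params) -> ImuStream:
    """Add a measurement-chain disturbance to an existing stream.

    ``spike``: an IC-like jerk pulse at ``at`` seconds with peak jerk
    ``amp`` (m/s³), added along the instantaneous acceleration direction
    so it lands on the rotated z axis.  ``dropout``: deletes samples in
    ``[start, start + duration)`` leaving a timestamp gap.  ``drift``: a
    linear gyro bias ramp on ``axis`` reaching ``rate`` °/s per second.
    """
    out = stream.copy()
    if kind == "spike":
        at = params["at"]
        amp = params.get("amp", 3000.0)
        direction = out.acc[np.searchsorted(out.t, at)].copy()
        nrm = np.linalg.norm(direction)
        direction = direction / nrm if nrm > 1e-9 else np.array([0.0, 0.0, 1.0])
        pulse = _raised_cosine_pulse(out.t, at, _IC_PULSE_S, amp)
        out.acc = out.acc + pulse[:, None] * direction[None, :]
        return out
    if kind == "dropout":
        start = params["start"]
        duration = params["duration"]
        if duration <= 0:
            return out
        keep = (out.t < start) | (out.t >= start + duration)
        out.t, out.acc, out.gyr = out.t[keep], out.acc[keep], out.gyr[keep]
        out.validate()
        return out
    if kind == "drift":
        axis = params.get("axis", 1)
        rate = params.get("rate", 1.0)
        out.gyr[:, axis] = out.gyr[:, axis] + rate * (out.t - out.t[0])
        return out
    raise ValueError(f"unknown disturbance kind {kind!r}")
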