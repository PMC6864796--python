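"""Streaming gait-event detection with a finite-state machine.

The detector consumes a foot-IMU stream sample by sample and emits the
four gait events per limb in fixed order:

* **Initial Contact (IC)** — the heel strike produces a sharp spike of the
  jerk (time derivative of acceleration) on the foot-frame z axis; an IC
  fires when |jerk| falls inside a *floating* band ``(jerk_min, jerk_max)``
  that is re-blended after every step from the previous band and a
  fraction of the current peak jerk.
* **Full Contact (FC)** — foot flat during midstance; all gyro components
  quiescent for ``k_fc`` consecutive samples (shared with the alignment
  stage, which refreshes the sensor-to-foot rotation here).
* **Heel Off (HO)** — the heel rise starts the pitch rotation: |ω_y|
  exceeds its threshold while all three accelerations stay quiet
  (``a_z`` gravity-corrected; comparator directions are configurable).
* **Toe Off (TO)** — three conditions satisfied *sequentially*: ω_y rises
  above a high threshold, then decreases strictly for ``k_to`` samples,
  then falls below a low threshold, where the event fires.

Out-of-sequence candidates are discarded by the state machine; temporal
gates (minimum swing time before an IC, minimum roll time before a HO)
suppress spurious spikes; the maximum swing pitch rate of each step
rescales the TO thresholds and the temporal gates for the next step, so
the detector follows the treadmill speed.  Device profiles capture the
differences between an exoskeleton trainer (lokomat) and an end-effector
trainer (lyra): the lyra produces much lower heel-strike jerk and extra
jerk spikes during swing, so its profile lowers the jerk band and enables
an angular-velocity band that rejects IC candidates while the foot is
still rotating.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .alignment import AlignmentConfig, OnlineAligner
from .imu_io import GRAVITY, EventKind, EventRecord, ImuStream

__all__ = [
    "DetectorConfig",
    "DetectorState",
    "GaitCycle",
    "DetectionResult",
    "GaitEventDetector",
    "jerk_series",
    "update_floating_threshold",
    "adapt_factor",
    "step_fsm",
    "detect_initial_contact",
    "detect_heel_off",
    "detect_toe_off",
    "process_stream",
    "FSM_STATES",
]

FSM_STATES = ("AwaitIC", "AwaitFC", "AwaitHO", "AwaitTO")
#: Which event each state accepts, and the state that follows it.
_FSM_NEXT = {
    "AwaitIC": (EventKind.IC, "AwaitFC"),
    "AwaitFC": (EventKind.FC, "AwaitHO"),
    "AwaitHO": (EventKind.HO, "AwaitTO"),
    "AwaitTO": (EventKind.TO, "AwaitIC"),
}


class DetectorConfig(BaseModel):
    """All thresholds, windows, temporal gates and the device profile.

    Only the sensor ranges (±16 g, ±2000 °/s, 500 Hz) and the qualitative rules come
    from the device documentation; every numeric default here is a
    package choice, exposed for calibration.
    """

    model_config = ConfigDict(extra="forbid")

    profile: Literal["lokomat", "lyra"] = "lokomat"
    # Initial Contact jerk band, m/s^3 (initial values; floating thereafter)
    jerk_min: float = Field(default=500.0, gt=0)
    jerk_max: float = Field(default=6000.0, gt=0)
    float_alpha: float = Field(default=0.3, ge=0.0, le=1.0)
    float_gamma_lo: float = Field(default=0.5, gt=0)
    float_gamma_hi: float = Field(default=1.5, gt=0)
    ic_peak_window_s: float = Field(default=0.05, gt=0)
    jerk_smooth_width: int = Field(default=1, ge=1)
    # temporal gates, seconds (at adaptation factor 1)
    min_swing_time: float = Field(default=0.25, gt=0)
    min_roll_time: float = Field(default=0.15, gt=0)
    # Heel Off conditions
    omega_heeloff_thresh_y: float = Field(default=30.0, gt=0)
    a_heeloff_thresh_x: float = Field(default=2.0, gt=0)
    a_heeloff_thresh_y: float = Field(default=2.0, gt=0)
    a_heeloff_thresh_z: float = Field(default=2.0, gt=0)
    heeloff_omega_exceeds: bool = True
    heeloff_acc_below: bool = True
    # Toe Off conditions, deg/s
    omega_threshold_high: float = Field(default=100.0, gt=0)
    omega_threshold_low: float = Field(default=50.0, gt=0)
    k_to: int = Field(default=10, gt=0)
    # lyra Initial-Contact angular-velocity band, deg/s
    ic_band_enabled: bool = False
    ic_band_lo: float = -30.0
    ic_band_hi: float = 30.0
    # speed adaptation
    omega_ref: float = Field(default=300.0, gt=0)
    adapt_min: float = Field(default=0.5, gt=0)
    adapt_max: float = Field(default=2.0, gt=0)
    # error handling
    max_gap_s: float = Field(default=0.05, gt=0)
    alignment: AlignmentConfig = Field(default_factory=AlignmentConfig)

    @model_validator(mode="after")
    def _check(self) -> "DetectorConfig":
        if self.jerk_min >= self.jerk_max:
            raise ValueError("jerk_min must be < jerk_max")
        if self.omega_threshold_low >= self.omega_threshold_high:
            raise ValueError("omega_threshold_low must be < omega_threshold_high")
        if self.float_gamma_lo >= self.float_gamma_hi:
            raise ValueError("float_gamma_lo must be < float_gamma_hi")
        if self.ic_band_lo >= self.ic_band_hi:
            raise ValueError("ic_band_lo must be < ic_band_hi")
        if self.adapt_min > self.adapt_max:
            raise ValueError("adapt_min must be <= adapt_max")
        return self

    @classmethod
    def for_profile(cls, profile: str, **overrides) -> "DetectorConfig":
        """Named preset for a device profile.

        ``lyra``: lower jerk band (the end-effector trainer produces much
        lower heel-strike jerk), a shorter swing gate, and the IC
        angular-velocity band enabled.  ``lokomat``: band disabled.
        """
        presets = {
            "lokomat": {},
            "lyra": {
                "jerk_min": 200.0,
                "jerk_max": 3000.0,
                "min_swing_time": 0.10,
                "ic_band_enabled": True,
            },
        }
        if profile not in presets:
            raise ValueError(f"unknown profile {profile!r}; expected one of {list(presets)}")
        kwargs = {"profile": profile, **presets[profile], **overrides}
        return cls(**kwargs)


@dataclass
class DetectorState:
    """Evolving detector state: FSM stage, floating band, gates, adaptation."""

    fsm: str = "AwaitIC"
    band: tuple[float, float] = (0.0, 0.0)
    last_to_time: float | None = None
    ic_time: float | None = None
    omega_max_last_to: float | None = None
    adaptation_factor: float = 1.0


@dataclass
class GaitCycle:
    """One IC-to-IC gait cycle: IC, FC, HO, TO plus the closing IC.

    ``valid`` is False when the cycle spans a sampling gap (missing data)
    — invalid cycles must never drive stimulation.
    """

    events: list[EventRecord]
    valid: bool = True
    reason: str = ""

    @property
    def side(self) -> str:
        return self.events[0].side

    @property
    def start(self) -> float:
        return self.events[0].t

    @property
    def end(self) -> float:
        return self.events[-1].t

    @property
    def duration(self) -> float:
        return self.end - self.start

    def time_of(self, kind: EventKind) -> float:
        for ev in self.events:
            if ev.kind == kind:
                return ev.t
        raise KeyError(kind)


@dataclass
class DetectionResult:
    """Everything a :func:`process_stream` run produces."""

    events: list[EventRecord]
    cycles: list[GaitCycle]
    discarded: list[EventRecord]
    state: DetectorState
    log: list[dict] | None = None

    @property
    def valid_cycles(self) -> list[GaitCycle]:
        return [c for c in self.cycles if c.valid]


# ---------------------------------------------------------------------------
# pure operations (also used by the streaming detector)

def jerk_series(stream: ImuStream, smooth_width: int = 1) -> np.ndarray:
    """Jerk of the foot-frame z acceleration, m/s³.

    First-order backward difference scaled by the sampling rate (causal,
    streaming-compatible); the first sample is 0.  ``smooth_width`` > 1
    applies a trailing moving average of that many samples.
    """
    az = stream.acc[:, 2]
    jerk = np.empty_like(az)
    jerk[0] = 0.0
    jerk[1:] = np.diff(az) * stream.fs
    if smooth_width > 1:
        csum = np.concatenate([[0.0], np.cumsum(jerk)])
        lo = np.maximum(0, np.arange(len(jerk)) - smooth_width + 1)
        hi = np.arange(1, len(jerk) + 1)
        jerk = (csum[hi] - csum[lo]) / (hi - lo)
    return jerk


def update_floating_threshold(
    band: tuple[float, float], peak_jerk: float, cfg: DetectorConfig
) -> tuple[float, float]:
    """Blend the jerk band toward fractions of the current step's peak jerk.

    ``lo' = (1-α)·lo + α·γ_lo·peak`` and analogously for the upper bound:
    the previous threshold is retained and a percentage of the current
    jerk is added, which keeps single outlier steps from capturing the
    band.  With α = 0 the band is frozen; with α = 1 it is fully replaced
    each step.
    """
    if peak_jerk <= 0:
        raise ValueError(f"peak jerk must be positive, got {peak_jerk}")
    a = cfg.float_alpha
    lo = (1 - a) * band[0] + a * cfg.float_gamma_lo * peak_jerk
    hi = (1 - a) * band[1] + a * cfg.float_gamma_hi * peak_jerk
    if lo >= hi:
        raise ValueError(f"floating threshold update produced empty band ({lo}, {hi})")
    return lo, hi


def adapt_factor(omega_max: float, cfg: DetectorConfig) -> float:
    """Speed-adaptation factor from the last swing's peak pitch rate.

    ``f = clamp(ω_max / ω_ref, adapt_min, adapt_max)``; the TO thresholds
    are scaled by ``f`` and the temporal gates by ``1/f``, so faster
    cycles raise the angular-velocity thresholds and shorten the gates.
    """
    if cfg.omega_ref <= 0:
        raise ValueError("omega_ref must be positive")
    return float(np.clip(omega_max / cfg.omega_ref, cfg.adapt_min, cfg.adapt_max))


def step_fsm(fsm: str, kind: EventKind) -> tuple[str, bool]:
    """Advance the finite-state machine with a candidate event.

    Returns ``(new_state, accepted)``; a candidate whose kind is not the
    one awaited is discarded and the state is unchanged.
    """
    if fsm not in _FSM_NEXT:
        raise ValueError(f"unknown FSM state {fsm!r}")
    expected, nxt = _FSM_NEXT[fsm]
    if EventKind(kind) is expected:
        return nxt, True
    return fsm, False


def _ic_condition(jerk: float, omega_y: float, band: tuple[float, float],
                  cfg: DetectorConfig) -> bool:
    if not (band[0] < abs(jerk) < band[1]):
        return False
    if cfg.ic_band_enabled and not (cfg.ic_band_lo <= omega_y <= cfg.ic_band_hi):
        return False
    return True


def _ho_condition(acc: np.ndarray, omega_y: float, cfg: DetectorConfig) -> bool:
    omega_ok = abs(omega_y) > cfg.omega_heeloff_thresh_y
    if not cfg.heeloff_omega_exceeds:
        omega_ok = not omega_ok
    acc_ok = (
        abs(acc[0]) < cfg.a_heeloff_thresh_x
        and abs(acc[1]) < cfg.a_heeloff_thresh_y
        and abs(acc[2] - GRAVITY) < cfg.a_heeloff_thresh_z
    )
    if not cfg.heeloff_acc_below:
        acc_ok = not acc_ok
    return omega_ok and acc_ok


def detect_initial_contact(
    jerk: Sequence[float],
    gyr_y: Sequence[float],
    t: Sequence[float],
    state: DetectorState,
    cfg: DetectorConfig,
) -> int | None:
    """First sample index where the Initial-Contact condition fires.

    Requires ``state.fsm == 'AwaitIC'``; honours the minimum-swing gate
    relative to ``state.last_to_time`` and, for the lyra profile, the
    angular-velocity band.
    """
    if state.fsm != "AwaitIC":
        return None
    band = state.band if state.band != (0.0, 0.0) else (cfg.jerk_min, cfg.jerk_max)
    gate = cfg.min_swing_time / state.adaptation_factor
    for i in range(len(jerk)):
        if state.last_to_time is not None and t[i] - state.last_to_time < gate:
            continue
        if _ic_condition(jerk[i], gyr_y[i], band, cfg):
            return i
    return None


def detect_heel_off(
    acc: np.ndarray,
    gyr_y: Sequence[float],
    t: Sequence[float],
    state: DetectorState,
    cfg: DetectorConfig,
) -> int | None:
    """First sample where the Heel-Off conditions fire (rotated data).

    Requires ``state.fsm == 'AwaitHO'`` and the minimum-roll gate since
    ``state.ic_time``.
    """
    if state.fsm != "AwaitHO":
        return None
    gate = cfg.min_roll_time / state.adaptation_factor
    for i in range(len(gyr_y)):
        if state.ic_time is not None and t[i] - state.ic_time < gate:
            continue
        if _ho_condition(np.asarray(acc[i]), gyr_y[i], cfg):
            return i
    return None


def detect_toe_off(
    gyr_y: Sequence[float],
    t: Sequence[float],
    state: DetectorState,
    cfg: DetectorConfig,
) -> int | None:
    """First sample where the three sequential Toe-Off conditions complete.

    ω_y must exceed the high threshold, then decrease strictly for
    ``k_to`` consecutive samples, then drop below the low threshold; the
    event index is the low-threshold crossing.  On success the maximum
    observed ω_y is stored in ``state.omega_max_last_to``.
    """
    if state.fsm != "AwaitTO":
        return None
    f = state.adaptation_factor
    high = cfg.omega_threshold_high * f
    low = cfg.omega_threshold_low * f
    stage = 0
    count = 0
    omega_max = -np.inf
    prev = None
    for i, w in enumerate(gyr_y):
        omega_max = max(omega_max, w)
        if stage == 0:
            if w > high:
                stage = 1
                count = 0
        elif stage == 1:
            if prev is not None and w < prev:
                count += 1
                if count >= cfg.k_to:
                    stage = 2
            else:
                count = 0
        if stage == 2 and w < low:
            state.omega_max_last_to = float(omega_max)
            return i
        prev = w
    return None


# ---------------------------------------------------------------------------
# streaming detector

class GaitEventDetector:
    """Online detector: alignment, rotation, event conditions, FSM, cycles.

    One instance per limb.  Feed samples with :meth:`step` or run a whole
    stream with :meth:`process`.
    """

    def __init__(self, cfg: DetectorConfig | None = None, side: str = "left",
                 fs: float = 500.0):
        self.cfg = cfg or DetectorConfig()
        self.side = side
        self.fs = fs
        self.aligner = OnlineAligner(self.cfg.alignment)
        self.state = DetectorState(band=(self.cfg.jerk_min, self.cfg.jerk_max))
        self.events: list[EventRecord] = []
        self.discarded: list[EventRecord] = []
        self.cycles: list[GaitCycle] = []
        self._open: list[EventRecord] = []
        self._gap_times: list[float] = []
        self._prev_acc: np.ndarray | None = None
        self._prev_t: float | None = None
        self._jerk_buf: list[float] = []
        # pending floating-band update: track the peak |jerk| shortly after an IC
        self._peak: float | None = None
        self._peak_deadline: float = 0.0
        # Toe-Off sequential-condition tracker
        self._to_stage = 0
        self._to_count = 0
        self._to_prev: float | None = None
        self._to_max = -np.inf
        self.log: list[dict] | None = None

    # -- helpers ----------------------------------------------------------

    def _emit(self, kind: EventKind, index: int, t: float) -> bool:
        candidate = EventRecord(kind=kind, side=self.side, index=index, t=t)
        new_state, accepted = step_fsm(self.state.fsm, kind)
        if not accepted:
            self.discarded.append(candidate)
            return False
        self.state.fsm = new_state
        self.events.append(candidate)
        if kind is EventKind.IC:
            self._close_and_open_cycle(candidate)
            self.state.ic_time = t
        elif kind is EventKind.TO:
            self.state.last_to_time = t
            self.state.adaptation_factor = adapt_factor(
                self.state.omega_max_last_to, self.cfg
            )
        if kind is not EventKind.IC:
            self._open.append(candidate)
        return True

    def _close_and_open_cycle(self, ic: EventRecord) -> None:
        if len(self._open) == 4:  # IC FC HO TO -> close with this IC
            events = self._open + [ic]
            start, end = events[0].t, ic.t
            gap = any(start < g <= end for g in self._gap_times)
            self.cycles.append(
                GaitCycle(events=events, valid=not gap,
                          reason="sampling gap within cycle" if gap else "")
            )
        self._open = [ic]

    # -- per-sample update ------------------------------------------------

    def step(self, index: int, t: float, acc_raw: np.ndarray, gyr_raw: np.ndarray) -> None:
        cfg = self.cfg
        st = self.state
        self.aligner.update(index, acc_raw, gyr_raw)
        rot = self.aligner.rotation

        gap = self._prev_t is not None and (t - self._prev_t) > cfg.max_gap_s
        if gap:
            self._gap_times.append(t)

        if rot is None:
            self._prev_acc, self._prev_t = np.asarray(acc_raw, float), t
            return
        R = rot.matrix
        acc = R @ np.asarray(acc_raw, float)
        gyr = R @ np.asarray(gyr_raw, float)

        if self._prev_acc is None or gap:
            jerk = 0.0
        else:
            # difference both samples under the *current* rotation so a
            # matrix refresh never manufactures a jerk spike
            prev_az = float(R[2] @ self._prev_acc)
            jerk = (acc[2] - prev_az) * self.fs
        if cfg.jerk_smooth_width > 1:
            self._jerk_buf.append(jerk)
            if len(self._jerk_buf) > cfg.jerk_smooth_width:
                self._jerk_buf.pop(0)
            jerk = float(np.mean(self._jerk_buf))

        # floating-band update once the post-IC peak window has elapsed
        if self._peak is not None:
            self._peak = max(self._peak, abs(jerk))
            if t >= self._peak_deadline:
                st.band = update_floating_threshold(st.band, self._peak, cfg)
                self._peak = None

        f = st.adaptation_factor
        fsm = st.fsm
        if fsm == "AwaitIC":
            gate_ok = (
                st.last_to_time is None
                or t - st.last_to_time >= cfg.min_swing_time / f
            )
            if gate_ok and _ic_condition(jerk, gyr[1], st.band, cfg):
                if self._emit(EventKind.IC, index, t):
                    self._peak = abs(jerk)
                    self._peak_deadline = t + cfg.ic_peak_window_s
        elif fsm == "AwaitFC":
            if self.aligner.quiescent_run >= cfg.alignment.k_fc:
                self._emit(EventKind.FC, index, t)
        elif fsm == "AwaitHO":
            gate_ok = st.ic_time is None or t - st.ic_time >= cfg.min_roll_time / f
            if gate_ok and _ho_condition(acc, gyr[1], cfg):
                if self._emit(EventKind.HO, index, t):
                    self._to_stage, self._to_count = 0, 0
                    self._to_prev, self._to_max = None, -np.inf
        elif fsm == "AwaitTO":
            w = gyr[1]
            self._to_max = max(self._to_max, w)
            if self._to_stage == 0:
                if w > cfg.omega_threshold_high * f:
                    self._to_stage, self._to_count = 1, 0
            elif self._to_stage == 1:
                if self._to_prev is not None and w < self._to_prev:
                    self._to_count += 1
                    if self._to_count >= cfg.k_to:
                        self._to_stage = 2
                else:
                    self._to_count = 0
            if self._to_stage == 2 and w < cfg.omega_threshold_low * f:
                st.omega_max_last_to = float(self._to_max)
                self._emit(EventKind.TO, index, t)
            self._to_prev = w

        if self.log is not None:
            self.log.append(
                {"index": index, "t": t, "fsm": st.fsm, "jerk": jerk,
                 "band_lo": st.band[0], "band_hi": st.band[1],
                 "adaptation": st.adaptation_factor}
            )
        self._prev_acc, self._prev_t = np.asarray(acc_raw, float), t

    def process(self, stream: ImuStream, debug: bool = False) -> DetectionResult:
        """Run the full stream through the detector."""
        self.fs = stream.fs
        self.side = stream.side
        if debug:
            self.log = []
        for i in range(len(stream)):
            self.step(i, float(stream.t[i]), stream.acc[i], stream.gyr[i])
        return DetectionResult(
            events=self.events, cycles=self.cycles, discarded=self.discarded,
            state=self.state, log=self.log,
        )


def process_stream(
    stream: ImuStream, cfg: DetectorConfig | None = None, debug: bool = False
) -> DetectionResult:
    """Detect gait events and assemble gait cycles for one stream.

    Online loop: maintain the sensor-to-foot rotation, rotate each
    incoming sample, run the stage-appropriate condition, step the FSM,
    and close an IC-to-IC cycle whenever a new Initial Contact arrives.
    A cycle is valid iff all four events occurred in order between
    consecutive ICs and no sampling gap falls inside it.
    """
    detector = GaitEventDetector(cfg, side=stream.side, fs=stream.fs)
    return detector.process(stream, debug=debug)
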