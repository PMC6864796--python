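"""FES trigger scheduling from detected gait cycles.

Each stimulated muscle is switched on and off at fixed percentages of
the gait cycle (a standard activation timing chart covering quadriceps,
biceps femoris, tibialis anterior and gastrocnemius for both sides).
Detected gait events anchor known percentages of the cycle, so any
percentage can be converted to a wall-clock switching time.

The scheduler is causal: when a cycle begins, its own duration is not
yet known, so within-cycle switching times are predicted from the
*previous* cycle's IC-to-IC duration.  The first cycle of a session
therefore produces no stimulation, and invalid cycles (missing events,
data gaps) never produce any — a mistimed pulse is hazardous, a missing
one is not.

Stimulator parameter sets are validated against the constraints of an
8-channel surface-electrode stimulator: current up to 130 mA in 5 mA
steps, frequency 10–50 Hz in 5 Hz steps, pulse width 20–500 µs in 10 µs
steps, biphasic rectangular pulses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .detection import GaitCycle
from .imu_io import EventKind

__all__ = [
    "TimingChartEntry",
    "TimingChart",
    "DEFAULT_ANCHORS",
    "StimParams",
    "StimulationSchedule",
    "phase_percent",
    "percent_to_time",
    "build_schedule",
    "validate_stim_params",
]

#: Cycle percentages the four events anchor (IC opens at 0, closes at 100).
DEFAULT_ANCHORS: dict[EventKind, float] = {
    EventKind.IC: 0.0,
    EventKind.FC: 8.0,
    EventKind.HO: 40.0,
    EventKind.TO: 60.0,
}


@dataclass(frozen=True)
class TimingChartEntry:
    """On/off percentages of the gait cycle for one muscle and side.

    ``start_pct > stop_pct`` denotes a wrap-around interval that crosses
    the cycle boundary (e.g. 90 -> 16 spans the terminal swing and the
    next cycle's loading response).
    """

    muscle: str
    side: str
    start_pct: float
    stop_pct: float

    def __post_init__(self) -> None:
        if not (0 <= self.start_pct <= 100 and 0 <= self.stop_pct <= 100):
            raise ValueError("percentages must lie in [0, 100]")
        if self.start_pct == self.stop_pct:
            raise ValueError("start_pct and stop_pct must differ")
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be 'left' or 'right', got {self.side!r}")

    @property
    def on_fraction(self) -> float:
        """Fraction of the cycle the channel is on: ((stop - start) mod 100)/100."""
        return ((self.stop_pct - self.start_pct) % 100.0) / 100.0


@dataclass
class TimingChart:
    """A set of per-muscle stimulation timing entries."""

    entries: list[TimingChartEntry] = field(default_factory=list)

    @classmethod
    def default(cls) -> "TimingChart":
        """The standard eight-channel chart for robot-assisted gait."""
        rows = [
            ("quadriceps_femoris", "left", 90, 16),
            ("quadriceps_femoris", "right", 40, 66),
            ("biceps_femoris", "left", 80, 12),
            ("biceps_femoris", "right", 30, 62),
            ("tibialis_anterior", "left", 56, 12),
            ("tibialis_anterior", "right", 6, 62),
            ("gastrocnemius", "left", 10, 50),
            ("gastrocnemius", "right", 60, 100),
        ]
        return cls([TimingChartEntry(m, s, float(a), float(b)) for m, s, a, b in rows])

    @classmethod
    def read_csv(cls, path: str | Path) -> "TimingChart":
        df = pd.read_csv(path)
        return cls(
            [
                TimingChartEntry(str(r.muscle), str(r.side),
                                 float(r.start_pct), float(r.stop_pct))
                for r in df.itertuples()
            ]
        )

    def write_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            [(e.muscle, e.side, e.start_pct, e.stop_pct) for e in self.entries],
            columns=["muscle", "side", "start_pct", "stop_pct"],
        ).to_csv(path, index=False)


@dataclass(frozen=True)
class StimParams:
    """One channel's stimulation parameters (validated separately)."""

    current: float  # mA
    frequency: float  # Hz
    pulse_width: float  # µs
    waveform: str = "biphasic rectangular"


def validate_stim_params(p: StimParams) -> list[str]:
    """Check a parameter set against the stimulator's constraints.

    Returns the list of violated constraints (empty = acceptable);
    violations are data, not exceptions.
    """
    violations = []
    if not (0 <= p.current <= 130):
        violations.append(f"current {p.current} mA outside [0, 130] mA")
    if p.current % 5 != 0:
        violations.append(f"current {p.current} mA not a multiple of 5 mA")
    if not (10 <= p.frequency <= 50):
        violations.append(f"frequency {p.frequency} Hz outside [10, 50] Hz")
    if p.frequency % 5 != 0:
        violations.append(f"frequency {p.frequency} Hz not a multiple of 5 Hz")
    if not (20 <= p.pulse_width <= 500):
        violations.append(f"pulse width {p.pulse_width} µs outside [20, 500] µs")
    if p.pulse_width % 10 != 0:
        violations.append(f"pulse width {p.pulse_width} µs not a multiple of 10 µs")
    if p.waveform != "biphasic rectangular":
        violations.append(f"waveform {p.waveform!r} is not 'biphasic rectangular'")
    return violations


def _anchor_points(cycle: GaitCycle, anchors: dict[EventKind, float]):
    """(time, percent) pairs through the cycle, closing IC at 100%."""
    pts = [(cycle.time_of(k), anchors[k]) for k in
           (EventKind.IC, EventKind.FC, EventKind.HO, EventKind.TO)]
    pts.append((cycle.events[-1].t, 100.0))
    return pts


def phase_percent(
    cycle: GaitCycle, t: float, anchors: dict[EventKind, float] | None = None
) -> float:
    """Percentage of the gait cycle at time ``t``, by anchor interpolation.

    Piecewise-linear through the event anchors (IC -> 0%, ..., closing
    IC -> 100%).
    """
    anchors = anchors or DEFAULT_ANCHORS
    pts = _anchor_points(cycle, anchors)
    times = [p[0] for p in pts]
    pcts = [p[1] for p in pts]
    if not (times[0] <= t <= times[-1]):
        raise ValueError(f"t={t} outside cycle span [{times[0]}, {times[-1]}]")
    return float(np.interp(t, times, pcts))


def percent_to_time(
    cycle: GaitCycle, pct: float, anchors: dict[EventKind, float] | None = None
) -> float:
    """Inverse of :func:`phase_percent` on the same cycle."""
    anchors = anchors or DEFAULT_ANCHORS
    pts = _anchor_points(cycle, anchors)
    times = [p[0] for p in pts]
    pcts = [p[1] for p in pts]
    if not (0.0 <= pct <= 100.0):
        raise ValueError(f"percentage {pct} outside [0, 100]")
    return float(np.interp(pct, pcts, times))


@dataclass
class StimulationSchedule:
    """Per-channel on/off intervals, seconds, non-overlapping per channel."""

    intervals: dict[tuple[str, str], list[tuple[float, float]]] = field(default_factory=dict)

    def channel(self, muscle: str, side: str) -> list[tuple[float, float]]:
        return self.intervals.get((muscle, side), [])

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (m, s, on, off)
            for (m, s), ivals in sorted(self.intervals.items())
            for on, off in ivals
        ]
        return pd.DataFrame(rows, columns=["muscle", "side", "on_time", "off_time"])

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.6f")


def build_schedule(
    cycles: list[GaitCycle],
    chart: TimingChart | None = None,
    anchors: dict[EventKind, float] | None = None,
) -> StimulationSchedule:
    """Derive per-muscle on/off times from detected cycles.

    For each chart entry and each valid cycle with a valid predecessor on
    the same side, the channel switches on at ``start_pct`` and off
    ``on_fraction`` of a cycle later, both predicted from the previous
    cycle's duration (a causal scheduler cannot know the current cycle's
    duration in advance).  Wrap-around entries close in the following
    cycle.  Invalid cycles produce no stimulation; an empty chart yields
    an empty schedule.  Idempotent: rebuilding from the same cycles gives
    the same schedule.
    """
    chart = chart if chart is not None else TimingChart.default()
    schedule = StimulationSchedule()
    by_side: dict[str, list[GaitCycle]] = {}
    for c in cycles:
        if c.valid:
            by_side.setdefault(c.side, []).append(c)
    for side, side_cycles in by_side.items():
        side_cycles.sort(key=lambda c: c.start)
    for entry in chart.entries:
        ivals: list[tuple[float, float]] = []
        side_cycles = by_side.get(entry.side, [])
        for prev, cur in zip(side_cycles, side_cycles[1:]):
            # require consecutive cycles: the predecessor must close where
            # the current one opens, otherwise its duration is stale
            if abs(prev.end - cur.start) > 1e-9:
                continue
            d_prev = prev.duration
            on = cur.start + entry.start_pct / 100.0 * d_prev
            off = on + entry.on_fraction * d_prev
            if ivals and on < ivals[-1][1]:
                on = ivals[-1][1]
            if off > on:
                ivals.append((on, off))
        if ivals:
            schedule.intervals[(entry.muscle, entry.side)] = ivals
    return schedule
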