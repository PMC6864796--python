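"""Data model and file I/O for foot-mounted IMU streams and gait-event tables.

The stream model mirrors the acquisition hardware: a 6-axis IMU (3-axis
accelerometer, ±16 g; 3-axis gyroscope, ±2000 °/s) sampled at a nominal
500 Hz.  Acceleration is carried in m/s², angular velocity in °/s
throughout the package — gyro thresholds in the detector are on the same
scale as the sensor range, so no silent unit conversions occur anywhere.

File dialect: comma-separated UTF-8 text with '.' decimal separator and a
single header line.  Streams use columns ``t,ax,ay,az,gx,gy,gz``; event
tables use ``kind,side,index,t``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GRAVITY",
    "ACC_RANGE",
    "GYR_RANGE",
    "EventKind",
    "ImuStream",
    "EventRecord",
    "FormatError",
    "read_stream",
    "write_stream",
    "read_events",
    "write_events",
]

#: Standard gravitational acceleration, m/s².
GRAVITY = 9.81
#: Accelerometer full-scale range, m/s² (±16 g).
ACC_RANGE = 16.0 * GRAVITY
#: Gyroscope full-scale range, °/s.
GYR_RANGE = 2000.0

STREAM_COLUMNS = ["t", "ax", "ay", "az", "gx", "gy", "gz"]
EVENT_COLUMNS = ["kind", "side", "index", "t"]


class FormatError(ValueError):
    """Raised when an input file or in-memory stream violates the format contract."""


class EventKind(str, Enum):
    """The four gait events detectable per limb with a foot-mounted IMU."""

    IC = "IC"  # Initial Contact (heel strike)
    FC = "FC"  # Full Contact (foot flat during midstance)
    HO = "HO"  # Heel Off (heel rise at terminal stance)
    TO = "TO"  # Toe Off (pre-swing)


@dataclass(frozen=True)
class EventRecord:
    """A single timestamped gait-event detection.

    Parameters
    ----------
    kind : EventKind
        Which gait event.
    side : str
        ``"left"`` or ``"right"``.
    index : int
        0-based sample ordinal within the stream the event was detected on.
    t : float
        Event time in seconds from stream start.
    """

    kind: EventKind
    side: str
    index: int
    t: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "kind", EventKind(self.kind))
        if self.side not in ("left", "right"):
            raise FormatError(f"side must be 'left' or 'right', got {self.side!r}")
        if self.index < 0:
            raise FormatError(f"event index must be >= 0, got {self.index}")


@dataclass
class ImuStream:
    """A timestamped 6-axis inertial time series at a fixed sampling rate.

    Attributes
    ----------
    t : ndarray, shape (n,)
        Sample times, seconds, strictly increasing.
    acc : ndarray, shape (n, 3)
        Acceleration in the sensor frame, m/s².
    gyr : ndarray, shape (n, 3)
        Angular velocity in the sensor frame, °/s.
    fs : float
        Nominal sampling rate, Hz (default 500).
    side : str
        Which foot the sensor is mounted on.
    label : str
        Free-text description.

    Notes
    -----
    Timestamps must be strictly increasing and the *median* spacing must be
    consistent with ``fs`` within 1%.  Individual gaps larger than one
    sample period are permitted: dropped samples (e.g. a lost Bluetooth
    link) leave gaps in an otherwise regular stream, and downstream error
    handling invalidates gait cycles that span them.
    """

    t: np.ndarray
    acc: np.ndarray
    gyr: np.ndarray
    fs: float = 500.0
    side: str = "left"
    label: str = ""

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.acc = np.asarray(self.acc, dtype=float)
        self.gyr = np.asarray(self.gyr, dtype=float)
        self.validate()

    def validate(self) -> None:
        n = len(self.t)
        if n < 1:
            raise FormatError("stream must contain at least one sample")
        if self.acc.shape != (n, 3) or self.gyr.shape != (n, 3):
            raise FormatError(
                f"acc/gyr must have shape ({n}, 3); got {self.acc.shape} / {self.gyr.shape}"
            )
        if self.fs <= 0:
            raise FormatError(f"sampling rate must be positive, got {self.fs}")
        if self.side not in ("left", "right"):
            raise FormatError(f"side must be 'left' or 'right', got {self.side!r}")
        if n > 1:
            dt = np.diff(self.t)
            if np.any(dt <= 0):
                row = int(np.argmax(dt <= 0)) + 1
                raise FormatError(f"timestamps not strictly increasing at row {row}")
            med = float(np.median(dt))
            if abs(med * self.fs - 1.0) > 0.01:
                raise FormatError(
                    f"median sample spacing {med:.6g}s inconsistent with fs={self.fs} Hz"
                )
        bad_acc = np.abs(self.acc) > ACC_RANGE + 1e-9
        if np.any(bad_acc):
            row = int(np.argwhere(bad_acc)[0, 0])
            raise FormatError(f"acceleration out of ±16 g sensor range at row {row}")
        bad_gyr = np.abs(self.gyr) > GYR_RANGE + 1e-9
        if np.any(bad_gyr):
            row = int(np.argwhere(bad_gyr)[0, 0])
            raise FormatError(f"angular velocity out of ±2000 °/s sensor range at row {row}")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def duration(self) -> float:
        """Span from first to last timestamp, seconds."""
        return float(self.t[-1] - self.t[0])

    def segment(self, start: int, stop: int) -> "ImuStream":
        """Return samples ``[start, stop)`` as a new stream."""
        if not (0 <= start < stop <= len(self)):
            raise IndexError(f"invalid segment [{start}, {stop}) for length {len(self)}")
        return replace(self, t=self.t[start:stop], acc=self.acc[start:stop],
                       gyr=self.gyr[start:stop])

    def copy(self) -> "ImuStream":
        return replace(self, t=self.t.copy(), acc=self.acc.copy(), gyr=self.gyr.copy())


def read_stream(path: str | Path, fs_override: float | None = None) -> ImuStream:
    """Read an IMU stream from a delimited text file.

    The file must have header columns ``t,ax,ay,az,gx,gy,gz`` with time in
    seconds, acceleration in m/s² and angular velocity in °/s.  The
    sampling rate is inferred from the median time spacing unless
    ``fs_override`` is given.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    missing = [c for c in STREAM_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    t = df["t"].to_numpy(dtype=float)
    if fs_override is not None:
        fs = float(fs_override)
    elif len(t) > 1:
        fs = 1.0 / float(np.median(np.diff(t)))
    else:
        fs = 500.0
    side = str(df["side"].iloc[0]) if "side" in df.columns else "left"
    return ImuStream(
        t=t,
        acc=df[["ax", "ay", "az"]].to_numpy(dtype=float),
        gyr=df[["gx", "gy", "gz"]].to_numpy(dtype=float),
        fs=fs,
        side=side,
        label=str(path),
    )


def write_stream(stream: ImuStream, path: str | Path) -> None:
    """Write a stream as CSV re-readable by :func:`read_stream` with identical values."""
    df = pd.DataFrame(
        {
            "t": stream.t,
            "ax": stream.acc[:, 0],
            "ay": stream.acc[:, 1],
            "az": stream.acc[:, 2],
            "gx": stream.gyr[:, 0],
            "gy": stream.gyr[:, 1],
            "gz": stream.gyr[:, 2],
            "side": stream.side,
        }
    )
    # repr-roundtrip float formatting keeps read(write(s)) bit-identical
    df.to_csv(path, index=False, float_format="%.17g")


def read_events(path: str | Path) -> list[EventRecord]:
    """Read a gait-event table (columns ``kind,side,index,t``)."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    events = []
    for i, row in df.iterrows():
        try:
            kind = EventKind(str(row["kind"]))
        except ValueError as exc:
            raise FormatError(f"{path}: unknown event kind {row['kind']!r} at row {i}") from exc
        events.append(EventRecord(kind=kind, side=str(row["side"]),
                                  index=int(row["index"]), t=float(row["t"])))
    return events


def write_events(events: Iterable[EventRecord], path: str | Path) -> None:
    """Write a gait-event table; an empty list yields a header-only file."""
    rows = [(e.kind.value, e.side, e.index, e.t) for e in events]
    pd.DataFrame(rows, columns=EVENT_COLUMNS).to_csv(path, index=False, float_format="%.17g")
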