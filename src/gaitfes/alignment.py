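"""Arbitrary sensor-to-foot alignment.

A foot-mounted IMU can be strapped on in any orientation; the detector,
however, reasons in the *foot* frame (x forward, y = pitch axis pointing
left, z up).  This module estimates the fixed sensor-to-foot rotation
matrix directly from the gait signal, with no prior knowledge of the
mounting:

1. **Full Contact detection** — during foot-flat midstance all three
   gyroscope components stay inside a small band for a run of ``k_fc``
   consecutive samples.
2. **z-axis** — at Full Contact the accelerometer measures only the
   gravity reaction, so the (window-averaged) acceleration vector gives
   the sensor-frame direction of "up".
3. **y-axis** — the heel rise after midstance rotates the foot about its
   pitch axis; summing the absolute angular velocity per axis over a
   window after Full Contact identifies the main rotation axis.
4. **x-axis** — the cross product of the two, followed by normalization
   and re-orthogonalization, yields a proper rotation matrix.

The estimate is refreshed at every Full Contact, so slow shifts of the
sensor on the foot are tracked automatically.

Two sign conventions are fixed here (the raw construction leaves them
free): ``z`` is oriented so that rotated resting acceleration comes out
at +9.81 m/s², and ``y`` is oriented so that heel-rise pitch velocity is
positive, which the Toe-Off conditions downstream rely on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from pydantic import BaseModel, ConfigDict, Field

from .imu_io import ImuStream

__all__ = [
    "AlignmentConfig",
    "AlignmentError",
    "DegenerateGeometryError",
    "RotationEstimate",
    "detect_full_contact",
    "estimate_z_axis",
    "estimate_y_axis",
    "build_rotation_matrix",
    "rotate_stream",
    "run_alignment",
    "align_stream",
    "OnlineAligner",
]

_AXES = ("x", "y", "z")


class AlignmentError(RuntimeError):
    """No usable Full Contact / rotation estimate could be produced."""


class DegenerateGeometryError(ValueError):
    """Zero or parallel axis vectors — the rotation matrix is undefined."""


class AlignmentConfig(BaseModel):
    """Tunables of the alignment stage.

    ``omega_fullcontact_thresh`` is the gyro quiescence band (°/s);
    ``k_fc`` the quiescence run length in samples; ``k_y`` the post-Full-
    Contact summation window (samples) that must span the heel-rise and
    swing rotation of the slowest supported cycle.
    """

    model_config = ConfigDict(extra="forbid")

    omega_fullcontact_thresh: float = Field(default=20.0, gt=0)
    k_fc: int = Field(default=50, gt=0)
    k_y: int = Field(default=325, gt=0)


@dataclass(frozen=True)
class RotationEstimate:
    """A sensor-to-foot rotation built from one Full Contact.

    ``matrix`` rows are the unit foot axes x̂, ŷ, ẑ expressed in the
    sensor frame; left-multiplying a sensor-frame vector maps it into the
    foot frame.  ``degenerate`` flags estimates whose pitch axis had to be
    chosen arbitrarily because no rotation was observed after the Full
    Contact (e.g. a resting stream).
    """

    matrix: np.ndarray
    source_index: int
    main_axis: str
    degenerate: bool = False

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        if m.shape != (3, 3):
            raise DegenerateGeometryError(f"rotation matrix must be 3x3, got {m.shape}")
        if not np.allclose(m @ m.T, np.eye(3), atol=1e-9) or not np.isclose(
            np.linalg.det(m), 1.0, atol=1e-9
        ):
            raise DegenerateGeometryError("matrix is not a proper rotation (R Rᵀ=I, det=+1)")
        if self.main_axis not in _AXES:
            raise ValueError(f"main_axis must be one of {_AXES}")

    def apply(self, vectors: np.ndarray) -> np.ndarray:
        """Rotate row vectors (shape (..., 3)) into the foot frame."""
        return np.asarray(vectors, dtype=float) @ self.matrix.T


def detect_full_contact(
    stream: ImuStream, start: int, cfg: AlignmentConfig
) -> int | None:
    """First index ≥ ``start`` at which gyro quiescence has held for ``k_fc`` samples.

    All three gyro components must satisfy |ω| < ``omega_fullcontact_thresh``
    for ``k_fc`` consecutive samples counted from ``start``; the returned
    index is the last sample of the first complete run.  Returns ``None``
    if the stream ends first.
    """
    if not (0 <= start < len(stream)):
        raise IndexError(f"start {start} outside stream of length {len(stream)}")
    quiet = np.all(np.abs(stream.gyr[start:]) < cfg.omega_fullcontact_thresh, axis=1)
    run = 0
    for off, q in enumerate(quiet):
        run = run + 1 if q else 0
        if run >= cfg.k_fc:
            return start + off
    return None


def estimate_z_axis(stream: ImuStream, fc_index: int, cfg: AlignmentConfig) -> np.ndarray:
    """Raw (un-normalized) gravity direction at a Full Contact.

    Averages acceleration over the ``k_fc`` quiescence window ending at
    ``fc_index`` — a single-sample gravity estimate would be dominated by
    sensor noise.
    """
    lo = max(0, fc_index - cfg.k_fc + 1)
    z = stream.acc[lo : fc_index + 1].mean(axis=0)
    if np.linalg.norm(z) < 1e-9:
        raise DegenerateGeometryError("zero-magnitude acceleration at Full Contact")
    return z


def estimate_y_axis(
    stream: ImuStream, fc_index: int, cfg: AlignmentConfig
) -> tuple[np.ndarray, str]:
    """Absolute per-axis gyro sums over ``(fc_index, fc_index + k_y]``.

    The component with the largest sum is the main rotation axis — the
    sensor axis closest to the foot's pitch axis — requiring no prior
    knowledge of the mounting.  Returns the (non-negative) sum vector and
    the main-axis name.
    """
    stop = fc_index + 1 + cfg.k_y
    if stop > len(stream):
        raise IndexError(
            f"y-axis window (fc={fc_index}, k_y={cfg.k_y}) exceeds stream length {len(stream)}"
        )
    window = stream.gyr[fc_index + 1 : stop]
    sums = np.abs(window.sum(axis=0))
    return sums, _AXES[int(np.argmax(sums))]


def build_rotation_matrix(
    z_raw: np.ndarray,
    y_raw: np.ndarray,
    source_index: int = 0,
    signed_y_sum: np.ndarray | None = None,
    degenerate: bool = False,
) -> RotationEstimate:
    """Assemble a proper rotation from raw z (gravity) and y (pitch) vectors.

    ``x = y_raw × z_raw``; all rows are normalized and ŷ is re-computed as
    ``ẑ × x̂`` so the matrix is orthonormal (the raw absolute-sum y vector
    is generally not perpendicular to z).  If ``signed_y_sum`` is given
    (the plain, signed gyro sum) the sign of ŷ is fixed so that the
    observed rotation maps to positive foot-frame pitch velocity.
    """
    z_raw = np.asarray(z_raw, dtype=float)
    y_raw = np.asarray(y_raw, dtype=float)
    nz = np.linalg.norm(z_raw)
    ny = np.linalg.norm(y_raw)
    if nz < 1e-12 or ny < 1e-12:
        raise DegenerateGeometryError("zero-length axis vector")
    x_raw = np.cross(y_raw, z_raw)
    nx = np.linalg.norm(x_raw)
    if nx < 1e-9 * ny * nz:
        raise DegenerateGeometryError("y and z axes are parallel")
    z_hat = z_raw / nz
    x_hat = x_raw / nx
    # x = y × z is already perpendicular to z; re-derive y to close the triad
    y_hat = np.cross(z_hat, x_hat)
    if signed_y_sum is not None and float(np.dot(y_hat, signed_y_sum)) < 0:
        y_hat = -y_hat
        x_hat = -x_hat
    matrix = np.vstack([x_hat, y_hat, z_hat])
    main_axis = _AXES[int(np.argmax(np.abs(y_raw)))]
    return RotationEstimate(
        matrix=matrix, source_index=source_index, main_axis=main_axis, degenerate=degenerate
    )


_FALLBACK_CANDIDATES = (
    np.array([0.0, 1.0, 0.0]),
    np.array([1.0, 0.0, 0.0]),
    np.array([0.0, 0.0, 1.0]),
)


def _fallback_y(z_hat: np.ndarray) -> np.ndarray:
    """Arbitrary pitch axis perpendicular to gravity for rotation-free streams."""
    for cand in _FALLBACK_CANDIDATES:
        proj = cand - np.dot(cand, z_hat) * z_hat
        if np.linalg.norm(proj) > 0.3:
            return proj
    raise DegenerateGeometryError("cannot construct fallback pitch axis")  # pragma: no cover


def _axis_min_sum(thresh: float, n: int) -> float:
    """Minimum |gyro sum| to trust the pitch-axis estimate over noise.

    Quiescence-band noise over ``n`` samples accumulates like sqrt(n); a
    true heel-rise rotation accumulates linearly and clears this easily.
    """
    return 2.0 * thresh * np.sqrt(max(1, n))


def _estimate_at(stream: ImuStream, fc_index: int, cfg: AlignmentConfig) -> RotationEstimate:
    """Full estimate pipeline at one Full Contact, with degenerate fallback.

    The *signed* per-axis gyro sums give the pitch axis direction (the
    absolute sums identify the main axis but scramble mixed-sign
    components under an arbitrary mounting); the overall sign is fixed
    inside :func:`build_rotation_matrix`.
    """
    z_raw = estimate_z_axis(stream, fc_index, cfg)
    stop = min(len(stream), fc_index + 1 + cfg.k_y)
    window = stream.gyr[fc_index + 1 : stop]
    signed = window.sum(axis=0) if len(window) else np.zeros(3)
    if np.max(np.abs(signed)) < _axis_min_sum(cfg.omega_fullcontact_thresh, len(window)):
        z_hat = z_raw / np.linalg.norm(z_raw)
        return build_rotation_matrix(
            z_raw, _fallback_y(z_hat), source_index=fc_index, degenerate=True
        )
    return build_rotation_matrix(z_raw, signed, source_index=fc_index, signed_y_sum=signed)


def rotate_stream(
    stream: ImuStream,
    rotation: RotationEstimate,
    from_index: int = 0,
    to_index: int | None = None,
) -> ImuStream:
    """Map samples ``[from_index, to_index)`` into the foot frame."""
    seg = stream.segment(from_index, len(stream) if to_index is None else to_index)
    seg.acc = rotation.apply(seg.acc)
    seg.gyr = rotation.apply(seg.gyr)
    return seg


def run_alignment(
    stream: ImuStream, cfg: AlignmentConfig | None = None
) -> list[tuple[RotationEstimate, tuple[int, int]]]:
    """Estimate one rotation per detected Full Contact with its validity span.

    Each estimate governs samples from its Full Contact until the next
    one; the first estimate additionally covers the stream prefix and the
    last runs to the stream end.  Raises :class:`AlignmentError` if the
    stream contains no Full Contact at all.
    """
    cfg = cfg or AlignmentConfig()
    fcs: list[int] = []
    start = 0
    thresh = cfg.omega_fullcontact_thresh
    while start < len(stream):
        fc = detect_full_contact(stream, start, cfg)
        if fc is None:
            break
        fcs.append(fc)
        # skip to the end of this quiescent stretch so each foot-flat yields one FC
        moving = np.any(np.abs(stream.gyr[fc + 1 :]) >= thresh, axis=1)
        nxt = np.argmax(moving) if moving.any() else None
        if nxt is None:
            break
        start = fc + 1 + int(nxt)
    if not fcs:
        raise AlignmentError("no Full Contact found in stream — cannot align")
    estimates = []
    for i, fc in enumerate(fcs):
        if fc + 1 + cfg.k_y > len(stream) and estimates:
            continue  # not enough trailing data to re-estimate; keep the previous one
        span_from = 0 if not estimates else fc
        estimates.append((_estimate_at(stream, fc, cfg), span_from))
    spans: list[tuple[RotationEstimate, tuple[int, int]]] = []
    for i, (est, span_from) in enumerate(estimates):
        span_to = estimates[i + 1][1] if i + 1 < len(estimates) else len(stream)
        spans.append((est, (span_from, span_to)))
    return spans


def align_stream(
    stream: ImuStream, cfg: AlignmentConfig | None = None
) -> tuple[ImuStream, list[tuple[RotationEstimate, tuple[int, int]]]]:
    """Rotate a whole stream into the foot frame (offline convenience).

    Spans governed by a degenerate estimate are substituted with the
    nearest non-degenerate one when available — offline, the yaw
    information from a later gait cycle may be borrowed for a leading
    rest phase, which the causal streaming detector cannot do.
    """
    spans = run_alignment(stream, cfg)
    valid = [e for e, _ in spans if not e.degenerate]
    out = stream.copy()
    for est, (lo, hi) in spans:
        use = est
        if est.degenerate and valid:
            use = min(valid, key=lambda v: abs(v.source_index - est.source_index))
        out.acc[lo:hi] = use.apply(stream.acc[lo:hi])
        out.gyr[lo:hi] = use.apply(stream.gyr[lo:hi])
    return out, spans


class OnlineAligner:
    """Causal, sample-by-sample alignment used by the streaming detector.

    Feed samples in order with :meth:`update`; a new rotation estimate
    becomes *effective* only once its post-Full-Contact summation window
    is complete (``k_y`` samples after the Full Contact) — exactly the
    information a real-time implementation would have.  ``update`` returns
    the index of a freshly detected Full Contact, or ``None``.
    """

    def __init__(self, cfg: AlignmentConfig | None = None):
        self.cfg = cfg or AlignmentConfig()
        self.rotation: RotationEstimate | None = None
        self._run = 0
        self._acc_window: list[np.ndarray] = []
        self._pending_fc: int | None = None
        self._pending_z: np.ndarray | None = None
        self._pending_sum = np.zeros(3)
        self._pending_n = 0
        self.full_contacts: list[int] = []

    def update(self, index: int, acc: np.ndarray, gyr: np.ndarray) -> int | None:
        cfg = self.cfg
        fc_fired: int | None = None
        quiet = bool(np.all(np.abs(gyr) < cfg.omega_fullcontact_thresh))
        if quiet:
            self._run += 1
            self._acc_window.append(np.asarray(acc, dtype=float))
            if len(self._acc_window) > cfg.k_fc:
                self._acc_window.pop(0)
            if self._run == cfg.k_fc:
                fc_fired = index
                self.full_contacts.append(index)
                z = np.mean(self._acc_window, axis=0)
                if np.linalg.norm(z) >= 1e-9:
                    self._pending_fc = index
                    self._pending_z = z
                    self._pending_sum = np.zeros(3)
                    self._pending_n = 0
        else:
            self._run = 0
            self._acc_window.clear()
        if self._pending_fc is not None and index > self._pending_fc:
            self._pending_sum += gyr
            self._pending_n += 1
            if self._pending_n >= cfg.k_y:
                self._finish_pending()
        return fc_fired

    @property
    def quiescent_run(self) -> int:
        """Length of the current gyro-quiescence run, in samples."""
        return self._run

    def _finish_pending(self) -> None:
        assert self._pending_z is not None and self._pending_fc is not None
        signed = self._pending_sum
        if np.max(np.abs(signed)) < _axis_min_sum(
            self.cfg.omega_fullcontact_thresh, self._pending_n
        ):
            z_hat = self._pending_z / np.linalg.norm(self._pending_z)
            est = build_rotation_matrix(
                self._pending_z, _fallback_y(z_hat),
                source_index=self._pending_fc, degenerate=True,
            )
        else:
            est = build_rotation_matrix(
                self._pending_z, signed, source_index=self._pending_fc, signed_y_sum=signed
            )
        # never replace a good estimate with a degenerate one
        if self.rotation is None or not est.degenerate or self.rotation.degenerate:
            self.rotation = est
        self._pending_fc = None
        self._pending_z = None
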