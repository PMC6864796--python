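"""Scoring the detector against reference events, and alignment verification.

Two verification procedures are implemented:

* **Shape comparison** for the alignment stage: signals are offset-removed
  and amplitude-normalized so their autocorrelation maximum equals 1,
  and the maximum of the cross-correlation between the reference and the
  rotated signal measures shape similarity (1 = identical shape).
* **Step scoring** over fixed windows of 75,000 samples (2.5 min at
  500 Hz), with per-window detection rate and type-1 error:

  .. math::

     \\text{detection rate} = \\frac{100}{N_{ref}}(N_{det} - N_{inc}),
     \\qquad
     \\text{type-1 error} = \\frac{100}{N_{ref}} N_{inc}

  Incorrect (type-1) detections can mistime electrical stimulation and
  are hazardous; missed steps (type-2) merely withhold it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import correlate

from .detection import GaitCycle
from .imu_io import EventKind, EventRecord, ImuStream

__all__ = [
    "DegenerateSignalError",
    "WindowResult",
    "normalize_signal",
    "autocorr_max",
    "cross_similarity",
    "match_steps",
    "detection_rate",
    "type1_error",
    "type2_error",
    "windowed_evaluation",
    "summarize_windows",
]

WINDOW_SAMPLES = 75_000  # 2.5 min at 500 Hz


class DegenerateSignalError(ValueError):
    """Constant signal — normalization undefined."""


def normalize_signal(x: np.ndarray) -> np.ndarray:
    """Remove the offset and normalize the amplitude of a signal.

    The mean is subtracted and the result divided by the square root of
    the maximum of its autocorrelation (the signal energy), after which
    the autocorrelation maximum equals 1 — "100% similarity" of the
    signal with itself, the baseline for cross-correlation comparison.
    Idempotent and scale-invariant.
    """
    x = np.asarray(x, dtype=float)
    centered = x - x.mean()
    energy = float(np.dot(centered, centered))
    if energy <= 1e-300:
        raise DegenerateSignalError("constant signal cannot be normalized")
    return centered / np.sqrt(energy)


def autocorr_max(x: np.ndarray) -> float:
    """Maximum of the (unnormalized) autocorrelation of a signal."""
    x = np.asarray(x, dtype=float)
    return float(correlate(x, x, mode="full").max())


def cross_similarity(
    ref: np.ndarray, test: np.ndarray, max_lag: int | None = None
) -> float:
    """Maximum cross-correlation of two normalized signals, in [-1, 1].

    Both inputs are normalized (offset removed, unit energy) internally;
    the maximum is taken over lags within ``± max_lag`` samples (default:
    half the shorter signal).  1 means identical shape regardless of
    amplitude or offset.
    """
    a = normalize_signal(ref)
    b = normalize_signal(test)
    cc = correlate(a, b, mode="full")
    zero = len(b) - 1  # index of lag 0
    if max_lag is None:
        max_lag = min(len(a), len(b)) // 2
    lo = max(0, zero - max_lag)
    hi = min(len(cc), zero + max_lag + 1)
    if lo >= hi:
        raise ValueError("length mismatch beyond the configured lag range")
    return float(cc[lo:hi].max())


def _ic_times(detected) -> np.ndarray:
    """Opening-IC times from a list of cycles, events, or raw times."""
    if len(detected) == 0:
        return np.array([])
    first = detected[0]
    if isinstance(first, GaitCycle):
        return np.array(sorted(c.events[0].t for c in detected if c.valid))
    if isinstance(first, EventRecord):
        return np.array(sorted(e.t for e in detected if e.kind == EventKind.IC))
    return np.sort(np.asarray(detected, dtype=float))


def match_steps(
    detected, reference, tol: float | None = None
) -> tuple[int, int, int]:
    """Greedy one-to-one matching of detected steps to reference steps.

    Steps are anchored on their opening Initial Contact.  Both arguments
    may be cycle lists, event lists, or arrays of IC times.  A detected
    step is *correct* if its IC lies within ``tol`` seconds of an
    unmatched reference IC (greedy, in time order), otherwise
    *incorrect*; unmatched reference ICs are *missed*.  ``tol`` defaults
    to 10% of the median reference cycle duration.

    Returns ``(correct, incorrect, missed)``.
    """
    det = _ic_times(detected)
    ref = _ic_times(reference)
    if tol is None:
        if len(ref) < 2:
            raise ValueError("cannot infer tolerance from fewer than 2 reference steps")
        tol = 0.1 * float(np.median(np.diff(ref)))
    i = j = correct = incorrect = 0
    while i < len(ref) and j < len(det):
        if abs(det[j] - ref[i]) <= tol:
            correct += 1
            i += 1
            j += 1
        elif det[j] < ref[i] - tol:
            incorrect += 1
            j += 1
        else:
            i += 1  # reference step missed
    incorrect += len(det) - j
    missed = len(ref) - correct
    return correct, incorrect, missed


def detection_rate(steps_reference: int, steps_detected: int, steps_incorrect: int) -> float:
    """Percentage of reference steps detected correctly.

    ``100 / reference * (detected - incorrect)``.
    """
    if steps_reference <= 0:
        raise ValueError("steps_reference must be positive")
    return 100.0 / steps_reference * (steps_detected - steps_incorrect)


def type1_error(steps_reference: int, steps_incorrect: int) -> float:
    """Percentage of reference steps shadowed by an incorrect detection.

    ``100 / reference * incorrect`` — hazardous errors: they can trigger
    stimulation at the wrong phase.
    """
    if steps_reference <= 0:
        raise ValueError("steps_reference must be positive")
    return 100.0 / steps_reference * steps_incorrect


def type2_error(steps_reference: int, steps_missed: int) -> float:
    """Percentage of reference steps missed entirely (non-hazardous)."""
    if steps_reference <= 0:
        raise ValueError("steps_reference must be positive")
    return 100.0 / steps_reference * steps_missed


@dataclass
class WindowResult:
    """Step scores over one evaluation window."""

    start_index: int
    window_samples: int
    steps_reference: int
    steps_detected: int
    steps_incorrect: int
    steps_missed: int
    detection_rate: float
    type1_error: float
    type2_error: float


def _rest_mask(stream: ImuStream, quiesc_thresh: float = 20.0) -> np.ndarray:
    return np.all(np.abs(stream.gyr) < quiesc_thresh, axis=1)


def windowed_evaluation(
    stream: ImuStream,
    detected,
    reference,
    window_samples: int = WINDOW_SAMPLES,
    n_windows: int | None = None,
    tol: float | None = None,
    quiesc_thresh: float = 20.0,
) -> list[WindowResult]:
    """Score consecutive fixed-size windows, each starting in a rest phase.

    The first window start snaps to the first quiescent (gyro at rest)
    sample; each subsequent window starts at the quiescent sample nearest
    to the previous window's end.  Steps whose reference IC falls inside
    a window are scored against detected steps in the same span.
    """
    rest = np.flatnonzero(_rest_mask(stream, quiesc_thresh))
    if len(rest) == 0:
        raise ValueError("stream contains no rest phase to anchor windows")
    if n_windows is None:
        n_windows = max(1, len(stream) // window_samples)
    det_times = _ic_times(detected)
    ref_times = _ic_times(reference)
    if tol is None:
        if len(ref_times) < 2:
            raise ValueError("cannot infer tolerance from fewer than 2 reference steps")
        tol = 0.1 * float(np.median(np.diff(ref_times)))

    results = []
    start = int(rest[0])
    for _ in range(n_windows):
        if start + window_samples > len(stream):
            raise ValueError(
                f"stream too short for {n_windows} windows of {window_samples} samples"
            )
        t_lo = float(stream.t[start])
        t_hi = float(stream.t[start + window_samples - 1])
        ref_w = ref_times[(ref_times >= t_lo) & (ref_times <= t_hi)]
        det_w = det_times[(det_times >= t_lo) & (det_times <= t_hi)]
        correct, incorrect, missed = match_steps(det_w, ref_w, tol=tol)
        n_ref = len(ref_w)
        results.append(
            WindowResult(
                start_index=start,
                window_samples=window_samples,
                steps_reference=n_ref,
                steps_detected=len(det_w),
                steps_incorrect=incorrect,
                steps_missed=missed,
                detection_rate=detection_rate(n_ref, len(det_w), incorrect)
                if n_ref else float("nan"),
                type1_error=type1_error(n_ref, incorrect) if n_ref else float("nan"),
                type2_error=type2_error(n_ref, missed) if n_ref else float("nan"),
            )
        )
        nxt = start + window_samples
        later = rest[rest >= nxt]
        start = int(later[0]) if len(later) else nxt
    return results


def summarize_windows(results: list[WindowResult]) -> dict[str, float]:
    """Mean ± sd of detection rate and type-1 error across windows."""
    dr = np.array([r.detection_rate for r in results], dtype=float)
    t1 = np.array([r.type1_error for r in results], dtype=float)
    return {
        "detection_rate_mean": float(np.nanmean(dr)),
        "detection_rate_sd": float(np.nanstd(dr, ddof=1)) if len(dr) > 1 else 0.0,
        "type1_error_mean": float(np.nanmean(t1)),
        "type1_error_sd": float(np.nanstd(t1, ddof=1)) if len(t1) > 1 else 0.0,
        "n_windows": len(results),
    }
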