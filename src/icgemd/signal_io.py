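"""Signal container, CSV I/O and preprocessing.

ICG recordings are commonly acquired at 2000 Hz and analyzed at 250 Hz after
anti-aliased decimation and Savitzky-Golay smoothing of order 3; both steps
are exposed here with the sampling-rate bookkeeping kept consistent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import resample_poly, savgol_filter


@dataclass(frozen=True)
class Signal:
    """A uniformly sampled real-valued series.

    Parameters
    ----------
    samples : ndarray
        Sample values (Ohm/s for dZ/dt; arbitrary units accepted).
    fs : float
        Sampling rate in Hz, > 0.
    label : str
        Free-text channel label.
    """

    samples: np.ndarray
    fs: float
    label: str = ""

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if samples.ndim != 1 or samples.size < 2:
            raise ValueError("signal must be a 1-D series of length >= 2")
        if not np.all(np.isfinite(samples)):
            bad = int(np.flatnonzero(~np.isfinite(samples))[0])
            raise ValueError(f"non-finite sample at index {bad}")

    def __len__(self) -> int:
        return int(self.samples.size)

    @property
    def duration_s(self) -> float:
        return len(self) / self.fs

    @property
    def time(self) -> np.ndarray:
        return np.arange(len(self)) / self.fs


def read_signal(path: str, column_name: str, fs: float) -> Signal:
    """Read one numeric column of a headered CSV file as a :class:`Signal`.

    Raises a descriptive error for a missing file, a missing column, or any
    non-numeric / NaN row (naming the first offending row).
    """
    if not fs > 0:
        raise ValueError(f"sampling rate must be positive, got {fs}")
    try:
        frame = pd.read_csv(path)
    except FileNotFoundError:
        raise FileNotFoundError(f"signal file not found: {path}") from None
    except pd.errors.EmptyDataError:
        raise ValueError(f"signal file is empty: {path}") from None
    if column_name not in frame.columns:
        raise KeyError(
            f"column {column_name!r} not in {path} (columns: {list(frame.columns)})"
        )
    values = pd.to_numeric(frame[column_name], errors="coerce").to_numpy(dtype=float)
    bad = np.flatnonzero(~np.isfinite(values))
    if bad.size:
        raise ValueError(
            f"column {column_name!r} of {path} has a non-numeric or NaN value "
            f"at data row {int(bad[0])}"
        )
    return Signal(values, fs=fs, label=column_name)


def write_signal(signal: Signal, path: str) -> None:
    """Write a signal as a one-column headered CSV."""
    label = signal.label or "signal"
    pd.DataFrame({label: signal.samples}).to_csv(path, index=False)


def resample_signal(signal: Signal, target_fs: float) -> Signal:
    """Downsample with polyphase decimation and a zero-phase anti-alias filter.

    Upsampling is out of scope; ``target_fs == fs`` returns the input
    unchanged. The rational rate ``target_fs / fs`` is approximated to within
    1e-9 by a small fraction.
    """
    if not target_fs > 0:
        raise ValueError(f"target sampling rate must be positive, got {target_fs}")
    if target_fs > signal.fs:
        raise ValueError(
            f"upsampling not supported (target {target_fs} Hz > input {signal.fs} Hz)"
        )
    if target_fs == signal.fs:
        return Signal(signal.samples.copy(), fs=signal.fs, label=signal.label)
    ratio = _rational_ratio(target_fs / signal.fs)
    out = resample_poly(signal.samples, up=ratio[0], down=ratio[1], padtype="line")
    return Signal(out, fs=target_fs, label=signal.label)


def _rational_ratio(x: float, max_den: int = 10_000) -> tuple[int, int]:
    """Best rational approximation p/q of ``x`` with q <= max_den."""
    from fractions import Fraction

    frac = Fraction(x).limit_denominator(max_den)
    if abs(float(frac) - x) > 1e-9:
        raise ValueError(f"rate ratio {x} has no small rational approximation")
    return frac.numerator, frac.denominator


def savgol_smooth(signal: Signal, order: int = 3, window_samples: int = 15) -> Signal:
    """Savitzky-Golay least-squares polynomial smoothing.

    The default window of 15 samples at 250 Hz spans about 60 ms, wide enough
    to suppress residual noise while preserving the sharp C upstroke. The
    window must be odd and strictly larger than the polynomial order.
    """
    if window_samples % 2 == 0:
        raise ValueError(f"window must be odd, got {window_samples}")
    if window_samples <= order:
        raise ValueError(
            f"window ({window_samples}) must exceed polynomial order ({order})"
        )
    if window_samples > len(signal):
        raise ValueError("window longer than the signal")
    out = savgol_filter(signal.samples, window_length=window_samples, polyorder=order)
    return Signal(out, fs=signal.fs, label=signal.label)


# ---------------------------------------------------------------------------
# annotation I/O


def write_annotations_csv(annotations, path: str) -> None:
    """Write per-beat fiducials as rows of beat,point,sample_index."""
    rows = []
    for i, beat in enumerate(annotations.beats):
        for point in ("b", "c", "x"):
            idx = getattr(beat, point)
            if idx is not None:
                rows.append({"beat": i, "point": point.upper(), "sample_index": idx})
    pd.DataFrame(rows, columns=["beat", "point", "sample_index"]).to_csv(
        path, index=False
    )


def read_annotations_csv(path: str, fs: float):
    """Read a beat,point,sample_index CSV back into annotations."""
    from .fiducial import Beat, FiducialAnnotations

    frame = pd.read_csv(path)
    for col in ("beat", "point", "sample_index"):
        if col not in frame.columns:
            raise KeyError(f"annotation file {path} lacks column {col!r}")
    beats = []
    for _, group in frame.groupby("beat", sort=True):
        points = {
            str(row["point"]).lower(): int(row["sample_index"])
            for _, row in group.iterrows()
        }
        if "c" not in points:
            continue
        beats.append(Beat(b=points.get("b"), c=points["c"], x=points.get("x")))
    return FiducialAnnotations(beats=beats, fs=fs)


def duration_drift_samples(original: Signal, processed: Signal) -> float:
    """Absolute duration difference expressed in processed-rate samples."""
    return abs(original.duration_s - processed.duration_s) * processed.fs


__all__ = [
    "Signal",
    "read_signal",
    "write_signal",
    "resample_signal",
    "savgol_smooth",
    "write_annotations_csv",
    "read_annotations_csv",
    "duration_drift_samples",
]
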