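"""Standard empirical mode decomposition (EMD).

The signal x(t) is split into intrinsic mode functions (IMFs) plus a residual,

    x(t) = sum_i C_i(t) + r_n(t),

by iterative *sifting*: cubic-spline envelopes are fitted through the local
maxima and minima, their mean is subtracted, and the process repeats until the
candidate satisfies the two IMF conditions — the extrema and zero-crossing
counts differ by at most one, and the local envelope mean is (numerically)
zero. Decomposition stops when the residual is constant, monotonic, or has at
most one extremum.

Numerical policy (the classical formulation leaves these open):

* sifting stops when the candidate passes :func:`is_imf`, with two
  fallbacks: the Cauchy step-size measure SD = sum((h_prev - h)^2) /
  sum(h_prev^2) dropping below ``sd_threshold`` (default 1e-8, i.e. the
  update has stagnated and further sifting cannot help), or
  ``max_sift_iters`` (logged);
* the envelope-mean condition is tested as max|m| <= 0.05 * RMS(h);
* boundaries are handled by mirroring the two nearest extrema at each end
  before spline fitting, which suppresses end swings that would corrupt
  fiducial timing near record edges;
* plateaus contribute their midpoint index once; an exact zero adopts the
  sign of the following sample when counting zero crossings.

All indices are 0-based and every series keeps the input length.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline

logger = logging.getLogger(__name__)

#: relative tolerance of the "envelope mean is zero" IMF condition
ENVELOPE_MEAN_TOLERANCE = 0.05


class InsufficientExtremaError(ValueError):
    """The series is monotonic or too flat to support envelope construction."""


@dataclass(frozen=True)
class SiftConfig:
    """Parameters of the sifting loop.

    ``sd_threshold`` is the Cauchy step-size stop; the default is set small
    so that the IMF conditions themselves govern stopping and the Cauchy
    measure only catches stagnation. Raise it to 0.2 for classical
    Cauchy-style sifting (faster, but modes then rarely satisfy the strict
    envelope-mean condition).
    """

    sd_threshold: float = 1e-8
    max_sift_iters: int = 100
    max_imfs: int = 12
    boundary_policy: str = "mirror"

    def __post_init__(self) -> None:
        if not self.sd_threshold > 0:
            raise ValueError("sd_threshold must be positive")
        if self.max_sift_iters < 1:
            raise ValueError("max_sift_iters must be >= 1")
        if self.max_imfs < 1:
            raise ValueError("max_imfs must be >= 1")
        if self.boundary_policy != "mirror":
            raise ValueError(f"unknown boundary policy {self.boundary_policy!r}")


@dataclass(frozen=True)
class IMFSet:
    """Ordered intrinsic mode functions plus the residual trend."""

    imfs: list[np.ndarray]
    residual: np.ndarray
    method: str  # "emd" or "eemd"
    fs: float

    def __post_init__(self) -> None:
        n = self.residual.size
        if any(imf.size != n for imf in self.imfs):
            raise ValueError("all IMFs and the residual must share one length")
        if self.method not in ("emd", "eemd"):
            raise ValueError(f"unknown method tag {self.method!r}")

    def __len__(self) -> int:
        return len(self.imfs)

    def reconstruct(self) -> np.ndarray:
        """Sum of all IMFs plus the residual."""
        out = self.residual.copy()
        for imf in self.imfs:
            out += imf
        return out

    def to_frame(self):
        """IMFs as CSV-friendly columns imf1..imfN plus 'residual'."""
        import pandas as pd

        data = {f"imf{i + 1}": imf for i, imf in enumerate(self.imfs)}
        data["residual"] = self.residual
        return pd.DataFrame(data)


# ---------------------------------------------------------------------------
# extrema and zero crossings


def _compress_plateaus(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Collapse runs of equal consecutive values to their midpoint index."""
    n = x.size
    change = np.flatnonzero(np.diff(x) != 0)
    starts = np.concatenate(([0], change + 1))
    ends = np.concatenate((change, [n - 1]))
    mids = (starts + ends) // 2
    return mids, x[starts]


def find_extrema(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Strict interior local maxima and minima, ascending.

    A plateau (run of equal samples) bordered by lower (higher) neighbours on
    both sides counts once, at its midpoint index.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 samples to find extrema")
    mids, vals = _compress_plateaus(x)
    if vals.size < 3:
        empty = np.array([], dtype=int)
        return empty, empty
    d = np.sign(np.diff(vals))
    interior = np.arange(1, vals.size - 1)
    maxima = mids[interior[(d[:-1] > 0) & (d[1:] < 0)]]
    minima = mids[interior[(d[:-1] < 0) & (d[1:] > 0)]]
    return maxima.astype(int), minima.astype(int)


def count_zero_crossings(x: np.ndarray) -> int:
    """Sign changes between consecutive samples; exact zeros adopt the sign
    of the following sample."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    # "zeros adopt the following sample's sign" is equivalent, for counting
    # sign changes, to dropping the zero samples altogether
    s = np.sign(x)
    s = s[s != 0]
    if s.size < 2:
        return 0
    return int(np.count_nonzero(np.diff(s)))


# ---------------------------------------------------------------------------
# envelopes


def _mirror_extend(
    idx: np.ndarray, val: np.ndarray, n: int
) -> tuple[np.ndarray, np.ndarray]:
    """Reflect up to two nearest extrema across each record edge."""
    left_i = (-idx[:2][::-1]).astype(float)
    left_v = val[:2][::-1]
    right_i = (2 * (n - 1) - idx[-2:][::-1]).astype(float)
    right_v = val[-2:][::-1]
    # drop duplicated knots when an extremum sits exactly on the edge
    xs = np.concatenate((left_i, idx.astype(float), right_i))
    ys = np.concatenate((left_v, val, right_v))
    xs, keep = np.unique(xs, return_index=True)
    return xs, ys[keep]


def compute_envelopes(
    x: np.ndarray,
    maxima: np.ndarray,
    minima: np.ndarray,
    boundary_policy: str = "mirror",
) -> tuple[np.ndarray, np.ndarray]:
    """Cubic-spline upper/lower envelopes through the extrema.

    Raises :class:`InsufficientExtremaError` when either envelope has fewer
    than two knots, which the sifting loop treats as "x is a residual".
    With exactly two knots the spline degenerates to the straight line
    through them.
    """
    if boundary_policy != "mirror":
        raise ValueError(f"unknown boundary policy {boundary_policy!r}")
    x = np.asarray(x, dtype=float)
    if len(maxima) < 2 or len(minima) < 2:
        raise InsufficientExtremaError(
            f"monotonic/insufficient extrema ({len(maxima)} maxima, "
            f"{len(minima)} minima)"
        )
    t = np.arange(x.size)
    upper = _spline_through(maxima, x[maxima], x.size)(t)
    lower = _spline_through(minima, x[minima], x.size)(t)
    return upper, lower


def _spline_through(idx: np.ndarray, val: np.ndarray, n: int):
    idx = np.asarray(idx)
    val = np.asarray(val)
    if idx.size == 2:
        # mirroring two lone knots would fabricate oscillation; use the line
        slope = (val[1] - val[0]) / (idx[1] - idx[0])
        return lambda t: val[0] + slope * (t - idx[0])
    xs, ys = _mirror_extend(idx, val, n)
    return CubicSpline(xs, ys, bc_type="not-a-knot")


def envelope_mean(upper: np.ndarray, lower: np.ndarray) -> np.ndarray:
    """Elementwise mean of the two envelopes, m(t) = (upper + lower) / 2."""
    upper = np.asarray(upper, dtype=float)
    lower = np.asarray(lower, dtype=float)
    if upper.shape != lower.shape:
        raise ValueError(
            f"envelope length mismatch: {upper.shape} vs {lower.shape}"
        )
    return (upper + lower) / 2.0


# ---------------------------------------------------------------------------
# IMF conditions and sifting


def is_imf(h: np.ndarray, mean_tolerance: float = ENVELOPE_MEAN_TOLERANCE) -> bool:
    """Test the two IMF conditions.

    1. |#extrema - #zero crossings| <= 1;
    2. max|envelope mean| <= ``mean_tolerance`` * RMS(h).
    """
    h = np.asarray(h, dtype=float)
    if h.size < 3:
        raise ValueError("need at least 3 samples")
    maxima, minima = find_extrema(h)
    n_ext = len(maxima) + len(minima)
    if len(maxima) < 2 or len(minima) < 2:
        return False
    if abs(n_ext - count_zero_crossings(h)) > 1:
        return False
    upper, lower = compute_envelopes(h, maxima, minima)
    m = envelope_mean(upper, lower)
    rms = float(np.sqrt(np.mean(h**2)))
    if rms == 0.0:
        return False
    return bool(np.max(np.abs(m)) <= mean_tolerance * rms)


def extract_imf(
    x: np.ndarray, config: SiftConfig = SiftConfig()
) -> tuple[np.ndarray, int]:
    """Sift one IMF out of ``x``.

    Returns the mode and the number of sifting iterations performed. Raises
    :class:`InsufficientExtremaError` when ``x`` is already residual-like.
    """
    h = np.asarray(x, dtype=float).copy()
    for iteration in range(1, config.max_sift_iters + 1):
        maxima, minima = find_extrema(h)
        if len(maxima) < 2 or len(minima) < 2:
            if iteration == 1:
                raise InsufficientExtremaError(
                    "input has too few extrema to sift an IMF"
                )
            # over-sifted into a residual-like shape: return the candidate
            logger.warning(
                "sifting produced a residual-like mode after %d iterations",
                iteration,
            )
            return h, iteration
        upper, lower = compute_envelopes(h, maxima, minima, config.boundary_policy)
        m = envelope_mean(upper, lower)
        # IMF conditions checked on h with the envelopes just computed
        n_ext = len(maxima) + len(minima)
        rms = float(np.sqrt(np.mean(h**2)))
        if (
            rms > 0
            and abs(n_ext - count_zero_crossings(h)) <= 1
            and np.max(np.abs(m)) <= ENVELOPE_MEAN_TOLERANCE * rms
        ):
            return h, iteration
        h_next = h - m
        denom = float(np.sum(h**2))
        sd = float(np.sum((h - h_next) ** 2)) / denom if denom > 0 else 0.0
        h = h_next
        if sd < config.sd_threshold:
            # fixed point reached with the IMF conditions still unmet
            # (e.g. an extrema/zero-crossing mismatch no sifting can fix)
            logger.warning(
                "sifting stagnated after %d iterations without satisfying "
                "the IMF conditions",
                iteration,
            )
            return h, iteration
    logger.warning(
        "sifting stopped at the %d-iteration cap without satisfying the "
        "IMF conditions",
        config.max_sift_iters,
    )
    return h, config.max_sift_iters


def _is_residual(r: np.ndarray) -> bool:
    """Constant, monotonic, or at most one extremum."""
    if r.size < 3 or np.ptp(r) == 0.0:
        return True
    maxima, minima = find_extrema(r)
    return len(maxima) + len(minima) <= 1 or len(maxima) < 2 or len(minima) < 2


def emd(
    x: np.ndarray | "object",
    config: SiftConfig = SiftConfig(),
    fs: float = 1.0,
) -> IMFSet:
    """Full empirical mode decomposition of a series.

    Accepts a plain array or a :class:`~icgemd.signal_io.Signal` (whose ``fs``
    then overrides the ``fs`` argument). Decomposition stops when the running
    residual is constant/monotonic/single-extremum or ``max_imfs`` is reached.
    The returned set reconstructs the input exactly (the residual is what is
    left after subtracting every IMF).
    """
    if hasattr(x, "samples"):
        fs = float(x.fs)
        x = x.samples
    x = np.asarray(x, dtype=float)
    if x.size < 4:
        raise ValueError("need at least 4 samples to decompose")
    imfs: list[np.ndarray] = []
    residual = x.copy()
    while len(imfs) < config.max_imfs and not _is_residual(residual):
        try:
            imf, iters = extract_imf(residual, config)
        except InsufficientExtremaError:
            break
        imfs.append(imf)
        residual = residual - imf
        logger.debug("IMF %d extracted in %d sifting iterations", len(imfs), iters)
    return IMFSet(imfs=imfs, residual=residual, method="emd", fs=fs)


__all__ = [
    "SiftConfig",
    "IMFSet",
    "InsufficientExtremaError",
    "find_extrema",
    "count_zero_crossings",
    "compute_envelopes",
    "envelope_mean",
    "is_imf",
    "extract_imf",
    "emd",
    "ENVELOPE_MEAN_TOLERANCE",
]
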