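"""Tolerance matching of detected fiducials against reference annotations.

A detected point matches a reference point when the two indices differ by at
most the tolerance (default 7 samples; at 250 Hz that is 28 ms, within the
conventional +/-30 ms agreement window used for ICG delineation). Matching
is one-to-one and greedy: references are visited in ascending order, each
takes its nearest unused detected candidate within tolerance (the earlier
candidate on an exact tie). When point trains are separated by more than
twice the tolerance — the normal beat-to-beat situation — this greedy
scheme coincides with optimal bipartite matching.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

from .fiducial import FiducialAnnotations

logger = logging.getLogger(__name__)

DEFAULT_TOLERANCE_SAMPLES = 7


@dataclass(frozen=True)
class MatchResult:
    """Outcome of matching one point type."""

    n_matched: int
    n_reference: int
    n_detected: int
    tolerance_samples: int
    errors_samples: list[int]
    accuracy_pct: float

    def to_dict(self) -> dict:
        return {
            "n_matched": self.n_matched,
            "n_reference": self.n_reference,
            "n_detected": self.n_detected,
            "tolerance_samples": self.tolerance_samples,
            "accuracy_pct": self.accuracy_pct,
            "median_abs_error_samples": (
                float(np.median(np.abs(self.errors_samples)))
                if self.errors_samples
                else None
            ),
        }


def percentage_accuracy(n_matched: int, n_reference: int) -> float:
    """100 * matched / reference, rounded half-up to 2 decimals."""
    if n_reference <= 0:
        raise ValueError("n_reference must be positive")
    pct = Decimal(100 * n_matched) / Decimal(n_reference)
    return float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def match_points(
    detected,
    reference,
    tolerance_samples: int = DEFAULT_TOLERANCE_SAMPLES,
) -> MatchResult:
    """One-to-one greedy nearest matching of two ascending index lists."""
    detected = np.asarray(detected, dtype=int)
    reference = np.asarray(reference, dtype=int)
    for name, arr in (("detected", detected), ("reference", reference)):
        if arr.size > 1 and np.any(np.diff(arr) < 0):
            raise ValueError(f"{name} indices must be ascending")

    used = np.zeros(detected.size, dtype=bool)
    errors: list[int] = []
    for r in reference:
        if not detected.size:
            break
        dist = np.abs(detected - r).astype(float)
        dist[used] = np.inf
        j = int(np.argmin(dist))  # argmin takes the earlier index on ties
        if dist[j] <= tolerance_samples:
            used[j] = True
            errors.append(int(detected[j] - r))

    n_matched = len(errors)
    accuracy = (
        percentage_accuracy(n_matched, reference.size) if reference.size else 0.0
    )
    return MatchResult(
        n_matched=n_matched,
        n_reference=int(reference.size),
        n_detected=int(detected.size),
        tolerance_samples=int(tolerance_samples),
        errors_samples=errors,
        accuracy_pct=accuracy,
    )


def median_difference(algorithm_values, expert_values) -> float:
    """median(algorithm) - median(expert), for median-vs-median comparison
    of a hemodynamic parameter between the algorithm and an expert."""
    algorithm_values = np.asarray(algorithm_values, dtype=float)
    expert_values = np.asarray(expert_values, dtype=float)
    if algorithm_values.size == 0 or expert_values.size == 0:
        raise ValueError("both value lists must be nonempty")
    return float(np.median(algorithm_values) - np.median(expert_values))


def tolerance_ms(tolerance_samples: int, fs: float) -> float:
    """The tolerance expressed in milliseconds at the given rate."""
    return 1000.0 * tolerance_samples / fs


def evaluate_annotations(
    detected: FiducialAnnotations,
    reference: FiducialAnnotations,
    tolerance_samples: int = DEFAULT_TOLERANCE_SAMPLES,
) -> dict[str, MatchResult]:
    """Match B, C and X trains separately; returns one result per type."""
    ms = tolerance_ms(tolerance_samples, reference.fs)
    logger.info(
        "matching with tolerance %d samples (%.1f ms at %g Hz)",
        tolerance_samples,
        ms,
        reference.fs,
    )
    return {
        point: match_points(
            detected.points(point), reference.points(point), tolerance_samples
        )
        for point in ("b", "c", "x")
    }


__all__ = [
    "MatchResult",
    "match_points",
    "percentage_accuracy",
    "median_difference",
    "tolerance_ms",
    "evaluate_annotations",
    "DEFAULT_TOLERANCE_SAMPLES",
]
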