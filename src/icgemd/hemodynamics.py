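"""Hemodynamic parameters from fiducial annotations.

Stroke volume follows the Kubicek formula

    SV = rho * (L^2 / Z0^2) * dZ/dt_max * LVET,

with rho the blood resistivity (Ohm*cm), L the inter-electrode thoracic
length (cm), Z0 the base impedance (Ohm), dZ/dt_max the signal amplitude at
C (Ohm/s) and LVET the B-to-X interval (s); the units collapse to cm^3 = mL.
Heart rate is the beat frequency implied by the mean inter-C interval and
cardiac output is mean SV times HR.

PEP (ECG Q to ICG B) and the Heather contractility index need an externally
supplied ECG Q annotation and are computed only when one is given. Beats
missing B or X yield no LVET/SV; they are reported as absent and excluded
from the aggregates rather than interpolated — clinical values are never
fabricated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fiducial import FiducialAnnotations, compute_cc_mean
from .signal_io import Signal


@dataclass(frozen=True)
class SubjectConstants:
    """Subject-specific constants of the Kubicek formula."""

    rho: float = 150.0  # blood resistivity, Ohm*cm
    L: float = 30.0  # inter-electrode thoracic length, cm
    Z0: float = 25.0  # base thoracic impedance, Ohm

    def __post_init__(self) -> None:
        if not (self.rho > 0 and self.L > 0 and self.Z0 > 0):
            raise ValueError("rho, L and Z0 must all be positive")


def lvet(b_idx: int, x_idx: int, fs: float) -> float:
    """Left-ventricular ejection time: the B-to-X interval in seconds."""
    if not b_idx < x_idx:
        raise ValueError(f"B ({b_idx}) must precede X ({x_idx})")
    return (x_idx - b_idx) / fs


def dzdt_max_at_c(signal: Signal, c_idx: int) -> float:
    """Signal amplitude at the C index (the maximum impedance-change rate)."""
    if not 0 <= c_idx < len(signal):
        raise IndexError(f"C index {c_idx} outside the signal")
    return float(signal.samples[c_idx])


def stroke_volume(consts: SubjectConstants, dzdt_max: float, lvet_s: float) -> float:
    """Kubicek stroke volume in mL."""
    if dzdt_max < 0 or lvet_s <= 0:
        raise ValueError("dzdt_max must be >= 0 and LVET > 0")
    return consts.rho * (consts.L**2 / consts.Z0**2) * dzdt_max * lvet_s


def heart_rate(c_indices: np.ndarray, fs: float) -> float:
    """Mean heart rate in bpm from the inter-C intervals."""
    return 60.0 * fs / compute_cc_mean(np.asarray(c_indices))


def cardiac_output(mean_sv_ml: float, hr_bpm: float) -> float:
    """Cardiac output in L/min."""
    if not (mean_sv_ml > 0 and hr_bpm > 0):
        raise ValueError("stroke volume and heart rate must be positive")
    return mean_sv_ml * hr_bpm / 1000.0


def pep(q_idx: int, b_idx: int, fs: float) -> float:
    """Pre-ejection period: ECG Q to ICG B, in seconds."""
    if not q_idx < b_idx:
        raise ValueError(f"Q ({q_idx}) must precede B ({b_idx})")
    return (b_idx - q_idx) / fs


def heather_index(dzdt_max: float, q_idx: int, c_idx: int, fs: float) -> float:
    """Heather contractility index: amplitude at C over the Q-to-C time.

    Units Ohm/s^2. The classical definition "C/(C-Q)" is read here as the C
    amplitude divided by the Q-to-C interval.
    """
    if not q_idx < c_idx:
        raise ValueError(f"Q ({q_idx}) must precede C ({c_idx})")
    return dzdt_max / ((c_idx - q_idx) / fs)


def compute_beat_metrics(
    signal: Signal,
    annotations: FiducialAnnotations,
    consts: SubjectConstants = SubjectConstants(),
    q_indices: np.ndarray | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Per-beat metrics table plus aggregate summary.

    The table has one row per beat with columns b, c, x, lvet_s, dzdt_max,
    sv_ml (NaN where B or X is absent) and, when ``q_indices`` is given (one
    Q per beat, NaN allowed), pep_s and heather. The summary dict carries
    hr_bpm, mean_sv_ml and co_l_min (None when not computable).
    """
    rows = []
    for i, beat in enumerate(annotations.beats):
        row: dict = {
            "beat": i,
            "b": beat.b,
            "c": beat.c,
            "x": beat.x,
            "lvet_s": np.nan,
            "dzdt_max": dzdt_max_at_c(signal, beat.c),
            "sv_ml": np.nan,
        }
        if beat.b is not None and beat.x is not None:
            row["lvet_s"] = lvet(beat.b, beat.x, annotations.fs)
            if row["dzdt_max"] >= 0:
                row["sv_ml"] = stroke_volume(consts, row["dzdt_max"], row["lvet_s"])
        if q_indices is not None:
            q = q_indices[i] if i < len(q_indices) else np.nan
            row["pep_s"] = np.nan
            row["heather"] = np.nan
            if np.isfinite(q):
                q = int(q)
                if beat.b is not None and q < beat.b:
                    row["pep_s"] = pep(q, beat.b, annotations.fs)
                if q < beat.c:
                    row["heather"] = heather_index(
                        row["dzdt_max"], q, beat.c, annotations.fs
                    )
        rows.append(row)
    table = pd.DataFrame(rows)

    summary: dict = {"n_beats": len(annotations)}
    c_idx = annotations.points("c")
    summary["hr_bpm"] = (
        heart_rate(c_idx, annotations.fs) if c_idx.size >= 2 else None
    )
    sv = table["sv_ml"].dropna() if len(table) else pd.Series(dtype=float)
    summary["mean_sv_ml"] = float(sv.mean()) if len(sv) else None
    if summary["hr_bpm"] and summary["mean_sv_ml"]:
        summary["co_l_min"] = cardiac_output(summary["mean_sv_ml"], summary["hr_bpm"])
    else:
        summary["co_l_min"] = None
    return table, summary


__all__ = [
    "SubjectConstants",
    "lvet",
    "dzdt_max_at_c",
    "stroke_volume",
    "heart_rate",
    "cardiac_output",
    "pep",
    "heather_index",
    "compute_beat_metrics",
]
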