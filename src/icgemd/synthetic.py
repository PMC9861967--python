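"""Synthetic ICG (dZ/dt) beat trains with analytic ground truth.

Each beat is a sum of Gaussian lobes reproducing the canonical dZ/dt
morphology: a small negative A-wave (atrial contraction), the dominant
positive C lobe (peak aortic flow), the negative X trough (aortic valve
closing) and a small positive O wave (diastolic filling). The ground-truth
fiducials are computed once from the noiseless template — C at the argmax,
B at the local minimum between the A-wave and the C upstroke (the onset
notch), X at the first local minimum after C — and then shifted per beat, so
added noise and baseline wander never move the truth.

Beats are placed at intervals drawn from 60/N(hr_mean, hr_sd) seconds
(truncated to > 0.3 s), with per-beat amplitude jitter applied as a uniform
scale (which leaves the extremum positions untouched). Everything is
reproducible from the spec's seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fiducial import Beat, FiducialAnnotations
from .signal_io import Signal

#: full widths at half maximum of the morphology lobes, s
LOBE_WIDTHS_S = {"a": 0.030, "c": 0.050, "x": 0.045, "o": 0.060}

#: Gaussian sigma corresponding to a full width at half maximum
_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

#: lobe centre times within one beat template, s; the A wave overlaps the
#: foot of the C upstroke so that their crossover forms the B onset notch
LOBE_CENTERS_S = {"a": 0.160, "c": 0.220, "x": 0.330, "o": 0.460}

#: template length, s
TEMPLATE_LEN_S = 0.580


@dataclass(frozen=True)
class SyntheticSpec:
    """Generator parameters.

    Defaults emulate a resting adult: 75 +/- 3 bpm, C amplitude 1.5 Ohm/s
    with mild beat-to-beat variation, shallow A/X/O waves, slow respiratory
    baseline wander at 0.3 Hz, white measurement noise.
    """

    fs: float = 250.0
    duration_s: float = 60.0
    hr_mean_bpm: float = 75.0
    hr_sd_bpm: float = 3.0
    c_amplitude: float = 1.5
    c_amplitude_sd: float = 0.1
    a_wave_amplitude: float = 0.25
    x_trough_depth: float = 0.5
    o_wave_amplitude: float = 0.2
    noise_sd: float = 0.0
    wander_amplitude: float = 0.1
    wander_freq_hz: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.fs > 0:
            raise ValueError("fs must be positive")
        if not self.duration_s > 0:
            raise ValueError("duration_s must be positive")
        if not 20 < self.hr_mean_bpm < 250:
            raise ValueError("hr_mean_bpm must lie in (20, 250)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def synth_beat_template(spec: SyntheticSpec) -> tuple[np.ndarray, int, int, int]:
    """One noiseless beat and its (b, c, x) offsets in samples.

    Raises when the requested amplitudes leave any fiducial unidentifiable
    (e.g. a zero C amplitude, or no post-C minimum).
    """
    if spec.c_amplitude <= 0:
        raise ValueError("c_amplitude must be positive to identify C")
    n = int(round(TEMPLATE_LEN_S * spec.fs))
    t = np.arange(n) / spec.fs

    def lobe(center: float, fwhm: float, amp: float) -> np.ndarray:
        sigma = fwhm * _FWHM_TO_SIGMA
        return amp * np.exp(-0.5 * ((t - center) / sigma) ** 2)

    wave = (
        -lobe(LOBE_CENTERS_S["a"], LOBE_WIDTHS_S["a"], spec.a_wave_amplitude)
        + lobe(LOBE_CENTERS_S["c"], LOBE_WIDTHS_S["c"], spec.c_amplitude)
        - lobe(LOBE_CENTERS_S["x"], LOBE_WIDTHS_S["x"], spec.x_trough_depth)
        + lobe(LOBE_CENTERS_S["o"], LOBE_WIDTHS_S["o"], spec.o_wave_amplitude)
    )

    c_off = int(np.argmax(wave))
    if wave[c_off] <= 0:
        raise ValueError("morphology has no positive C lobe")

    # B: the onset notch — the last local minimum before the C upstroke,
    # formed where the A-wave tail crosses into the rising C lobe
    b_off = None
    for i in range(c_off - 1, 1, -1):
        if wave[i] < wave[i - 1] and wave[i] <= wave[i + 1]:
            b_off = i
            break
    if b_off is None or not b_off < c_off:
        raise ValueError("morphology has no identifiable B notch before C")

    # X: the first strict local minimum after C
    x_off = None
    for i in range(c_off + 1, n - 1):
        if wave[i] < wave[i - 1] and wave[i] <= wave[i + 1]:
            x_off = i
            break
    if x_off is None:
        raise ValueError("morphology has no post-C minimum to serve as X")
    return wave, b_off, c_off, x_off


def synth_signal(spec: SyntheticSpec) -> tuple[Signal, FiducialAnnotations]:
    """Generate a beat train plus its ground-truth annotations."""
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration_s * spec.fs))
    template, b_off, c_off, x_off = synth_beat_template(spec)
    tlen = template.size
    if n < tlen:
        raise ValueError(
            f"duration {spec.duration_s}s too short for one beat "
            f"({tlen / spec.fs:.2f}s)"
        )

    samples = np.zeros(n)
    beats: list[Beat] = []
    onset = 0
    while onset + tlen <= n:
        scale = max(0.1, rng.normal(1.0, spec.c_amplitude_sd / spec.c_amplitude))
        samples[onset : onset + tlen] += scale * template
        beats.append(Beat(b=onset + b_off, c=onset + c_off, x=onset + x_off))
        interval_s = max(0.3, 60.0 / rng.normal(spec.hr_mean_bpm, spec.hr_sd_bpm))
        onset += int(round(interval_s * spec.fs))

    if not beats:
        raise ValueError("duration too short to place a single beat")

    t = np.arange(n) / spec.fs
    phase = rng.uniform(0, 2 * np.pi)
    samples += spec.wander_amplitude * np.sin(
        2 * np.pi * spec.wander_freq_hz * t + phase
    )
    if spec.noise_sd > 0:
        samples += rng.normal(0.0, spec.noise_sd, size=n)

    signal = Signal(samples, fs=spec.fs, label="synthetic_icg")
    return signal, FiducialAnnotations(beats=beats, fs=spec.fs)


def noise_sd_for_snr(spec: SyntheticSpec, snr_db: float) -> float:
    """Noise standard deviation that yields the requested SNR (dB) against
    the clean (noise-free, wander-free) beat train of ``spec``."""
    from dataclasses import replace

    clean, _ = synth_signal(replace(spec, noise_sd=0.0, wander_amplitude=0.0))
    rms = float(np.sqrt(np.mean(clean.samples**2)))
    return rms / 10 ** (snr_db / 20.0)


def empirical_snr_db(noisy: Signal, clean: Signal) -> float:
    """Measured SNR of a generated record against its clean counterpart."""
    noise = noisy.samples - clean.samples
    return 10.0 * np.log10(
        float(np.mean(clean.samples**2)) / float(np.mean(noise**2))
    )


__all__ = [
    "SyntheticSpec",
    "synth_beat_template",
    "synth_signal",
    "noise_sd_for_snr",
    "empirical_snr_db",
    "LOBE_WIDTHS_S",
    "LOBE_CENTERS_S",
]
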