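"""Generate a synthetic ICG record and delineate its B, C and X points.

The generator places Gaussian-lobe beats (A wave, C lobe, X trough, O wave)
at jittered intervals and knows the true fiducials by construction; the
detector must recover them from the signal alone via EMD/EEMD mode
combinations. Accuracy is the fraction of reference points matched within
+/-7 samples (28 ms at 250 Hz).
"""

import dataclasses

from icgemd import EnsembleConfig, SyntheticSpec, detect_fiducials, synth_signal
from icgemd.evaluation import evaluate_annotations
from icgemd.signal_io import savgol_smooth
from icgemd.synthetic import noise_sd_for_snr

spec = SyntheticSpec(duration_s=60.0, hr_mean_bpm=75.0, seed=1)
spec = dataclasses.replace(spec, noise_sd=noise_sd_for_snr(spec, 20.0))
signal, truth = synth_signal(spec)
print(f"simulated {signal.duration_s:.0f} s at {signal.fs:.0f} Hz, "
      f"{len(truth)} beats, 20 dB SNR")

preprocessed = savgol_smooth(signal)
annotations = detect_fiducials(
    preprocessed, ens_cfg=EnsembleConfig(n_realizations=100, seed=2)
)
print(f"detected {len(annotations)} beats")

for point, result in evaluate_annotations(annotations, truth).items():
    d = result.to_dict()
    print(f"  {point.upper()}: {d['accuracy_pct']:.2f}% matched "
          f"({result.n_matched}/{result.n_reference}), "
          f"median |error| {d['median_abs_error_samples']} samples")
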