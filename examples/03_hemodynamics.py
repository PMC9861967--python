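"""From fiducial annotations to hemodynamic parameters.

LVET is the B-to-X interval, dZ/dt_max the amplitude at C, and stroke
volume follows the Kubicek formula SV = rho * L^2/Z0^2 * dZ/dt_max * LVET
with subject constants rho (blood resistivity), L (electrode distance) and
Z0 (base thoracic impedance). Cardiac output is mean SV times heart rate.
"""

import dataclasses

from icgemd import (
    EnsembleConfig,
    SubjectConstants,
    SyntheticSpec,
    compute_beat_metrics,
    detect_fiducials,
    synth_signal,
)
from icgemd.signal_io import savgol_smooth
from icgemd.synthetic import noise_sd_for_snr

spec = SyntheticSpec(duration_s=60.0, seed=5)
spec = dataclasses.replace(spec, noise_sd=noise_sd_for_snr(spec, 20.0))
signal, _ = synth_signal(spec)
annotations = detect_fiducials(
    savgol_smooth(signal), ens_cfg=EnsembleConfig(n_realizations=100, seed=6)
)

consts = SubjectConstants(rho=150.0, L=30.0, Z0=25.0)
table, summary = compute_beat_metrics(signal, annotations, consts)

print(table[["b", "c", "x", "lvet_s", "dzdt_max", "sv_ml"]].head(5).round(3))
print(f"\nbeats: {summary['n_beats']}")
print(f"heart rate: {summary['hr_bpm']:.1f} bpm")
print(f"mean stroke volume: {summary['mean_sv_ml']:.1f} mL")
print(f"cardiac output: {summary['co_l_min']:.2f} L/min")
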