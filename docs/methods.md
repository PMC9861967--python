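# Methods

## Empirical mode decomposition

A series x(t) is decomposed as `x(t) = Σᵢ Cᵢ(t) + r(t)` where each
intrinsic mode function Cᵢ satisfies two conditions: its numbers of extrema
and zero crossings differ by at most one, and the mean of its upper and
lower cubic-spline envelopes is (numerically) zero. Modes are obtained by
sifting — subtracting the envelope mean repeatedly — and decomposition
stops when the residual is constant, monotonic, or has at most one
extremum. Subtraction makes reconstruction exact by construction; the test
suite asserts it to 1e-9 relative.

Numerical choices the classical formulation leaves open:

- **Envelope-mean tolerance.** "Zero mean" is tested as
  max|m(t)| ≤ 0.05 · RMS(h). Without a tolerance no finite-precision series
  would ever qualify.
- **Stopping.** Sifting stops when the candidate passes the IMF conditions;
  a Cauchy step-size guard (`sd_threshold`, default 1e-8) catches fixed
  points that the conditions can never satisfy (e.g. a slow tail with an
  extrema/zero-crossing mismatch and an already-zero envelope mean), and a
  100-iteration cap bounds the loop. Both fallbacks are logged. The
  classical alternative — stopping when the Cauchy measure falls below
  0.2 — leaves most modes short of the strict envelope-mean condition; it
  remains available by raising `sd_threshold`.
- **Boundaries.** The two nearest extrema are mirrored across each record
  edge before spline fitting, suppressing end swings that would corrupt
  fiducial timing. With only two extrema of a kind, the envelope
  degenerates to the straight line through them (mirroring lone knots
  would fabricate oscillation).
- **Conventions.** Plateaus contribute one extremum at their midpoint;
  exact zeros adopt the following sample's sign when counting crossings;
  indices are 0-based; every operation preserves series length.

## Ensemble EMD

EEMD decomposes `n_realizations` (default 100) noise-perturbed copies of
the input — white Gaussian noise with standard deviation
`noise_fraction · std(x)`, default 0.2 — and averages the modes order by
order. Realizations that stop early contribute zeros for the missing high
orders, which keeps the mode-wise mean well defined. Per-realization noise
streams are spawned from the master seed by realization index, so results
are independent of execution order. Averaged modes are not IMFs in the
strict sense (averaging destroys the envelope-mean property) and the
reconstruction identity holds against the ensemble mean of the noisy
inputs, not the original signal; with zero noise every realization is
identical and the result equals plain EMD exactly.

Ensemble realizations sift with the classical Cauchy-0.2 stop
(`eemd.REALIZATION_SIFT`): driving each noisy copy to the strict
envelope-mean condition would multiply the cost ~4× for a property the
averaging then destroys anyway.

## Fiducial detection

The delineation pipeline (also Cauchy-0.2 sifting, `DELINEATION_SIFT` —
the detectors rely on the mode structure that depth produces; deeper
sifting redistributes beat energy across modes and, measured on the
synthetic condition below, collapses B accuracy):

1. **C.** Plain EMD of the preprocessed signal;
   `cf1 = |(IMF₁+IMF₂+IMF₃+IMF₄)·(IMF₁·IMF₂·IMF₃)|`. Candidate peaks are
   cf1 local maxima; acceptance uses a two-level adaptive threshold in the
   Pan–Tompkins style: exponential moving averages (weight 0.125) of
   accepted-peak and rejected-candidate amplitudes, with
   `Th = noise + 0.5·(peak − noise)`. Because cf1 is a product of four
   mode amplitudes, level tracking runs on its fourth root (a monotone
   transform restoring a linear amplitude scale). Delineation being
   offline, the levels are initialized from an Otsu two-class split of all
   candidate amplitudes — robust both to inflated boundary beats and to
   noise maxima outnumbering beats — and a searchback pass at half
   threshold fills gaps longer than 1.66× the running beat-period
   estimate. A 200 ms refractory period separates accepted detections;
   within it the larger peak survives (the earlier on an exact tie).
   Detected peaks are then snapped to the dZ/dt maximum by hill-climbing
   in ±40 ms windows (C is by definition the cycle's greatest amplitude),
   and snapped detections with amplitude below 0.4× the median beat
   amplitude are discarded as A/O-wave sidelobes.
2. **B.** EEMD of the same signal; B is the nearest local maximum of
   d(IMF₄)/dt before C, searched up to 300 ms back (a generous bound on
   pre-ejection timing); absent if none.
3. **X.** First local minimum of `cf2 = IMF₃ + 2·IMF₄ + 4·IMF₅` strictly
   inside `IntX = [C, C + 0.15·CC_mean]` (round-half-up on the bound,
   clipped to the record). If cf2 is monotone across the window the
   interval minimum is taken; fewer than five ensemble modes are padded
   with zeros (logged). X reconciles two readings — "first minimum after
   C" and the bounded interval — as: first interior local minimum, with
   the interval-minimum fallback.

Beats missing B or X near record edges carry absent entries; beats without
a detected C are never emitted; within each beat b < c < x holds by
construction.

## Preprocessing

Recordings are decimated to the analysis rate (canonically 2000 → 250 Hz)
by polyphase filtering with a zero-phase anti-alias filter — chosen over
IIR decimation to avoid phase lag that would bias fiducial timing — and
smoothed with a Savitzky–Golay filter of order 3. The window is fixed at
15 samples (≈60 ms at 250 Hz): wide enough to suppress residual broadband
noise, narrow enough to preserve the C upstroke. Both are configurable;
window adaptivity was considered and left out of scope, as no principled
adaptation rule is established for this waveform.

## Synthetic generator

Each beat is a sum of four Gaussian lobes: negative A wave, dominant
positive C lobe, negative X trough, small positive O wave. Widths are full
widths at half maximum (A 30, C 50, X 45, O 60 ms) — read as FWHM rather
than Gaussian σ because a σ = 50 ms C lobe would imply a ≳150 ms upstroke,
far slower than any physiological dZ/dt. Lobe centres (A 160, C 220,
X 330, O 460 ms into the template) place the A wave against the foot of
the C upstroke so their crossover forms the B onset notch (C−B ≈ 60 ms)
and put X ≈ 110 ms after C, inside the 0.15·RR search bound the X detector
itself imposes at resting heart rates.

Ground truth is computed once on the noiseless template — C at the argmax,
B at the last local minimum before C, X at the first local minimum after
C — and shifted per beat; noise and baseline wander are added afterwards
and never move the truth. Beats are placed at intervals
60/N(hr_mean, hr_sd) s (defaults 75 ± 3 bpm, truncated to > 0.3 s), with
per-beat amplitude jitter applied as a uniform scale (extrema positions are
scale-invariant). Defaults: C amplitude 1.5 (arbitrary Ω/s units) with
sd 0.1, A 0.25, X depth 0.5, O 0.2; baseline wander 0.1 at 0.3 Hz
(respiratory); white noise of configurable sd, with `noise_sd_for_snr`
mapping a target SNR in dB to a noise level against the clean beat train.

What the generator does *not* emulate: arrhythmia, ectopic beats,
low-amplitude or multi-notch B-point morphologies, motion artifacts,
respiration-modulated beat amplitude, electrode impedance drift beyond a
single sinusoidal wander. Passing tests on this generator therefore show
that the mode-combination detectors recover the canonical morphology at
realistic noise levels; they do not certify performance on pathological
recordings.

## Evaluation

Detected and reference trains are matched one-to-one, greedily in
ascending reference order, each reference taking its nearest unused
detected candidate within tolerance (earlier index on ties). The default
tolerance is 7 samples — 28 ms at 250 Hz, inside the conventional ±30 ms
agreement window; the millisecond equivalent is logged. When inter-point
spacing exceeds twice the tolerance (the normal beat-to-beat situation)
greedy matching coincides with optimal bipartite matching; the test suite
asserts count symmetry and monotonicity in tolerance. Accuracy is
100·matched/reference, rounded half-up to two decimals. Median parameter
comparisons report median(algorithm) − median(expert).

## Problem sizes

The recovery experiment in `scripts/acceptance.py` and the acceptance test
uses a 120 s record at 250 Hz (≈149 beats) at 20 dB SNR with a
100-realization ensemble; the reconstruction check uses 50 random signals
of 256–4096 samples. These sizes give stable statistics (the binding rates
are 100% across seeds) while keeping a full run under a minute on one CPU.

## Known limitations

- Strictly noiseless records can drop an isolated beat: without noise
  dithering, EMD occasionally fragments one beat's energy across modes so
  its cf1 peak falls under threshold (the same pathology that motivates
  EEMD). Any realistic measurement noise removes the effect; C sensitivity
  at 20 dB SNR is 100% in the shipped experiments.
- The B rule (first d(IMF₄)/dt maximum before C) and the cf2 weights are
  tied to the mode ordering of 250 Hz adult recordings; signals at very
  different rates or heart rates may place the beat oscillation in a
  different mode index.
- The Heather index is computed as amplitude-at-C over the Q-to-C time;
  the classical "C/(C−Q)" shorthand is ambiguous between that and an index
  ratio, so the computation sits behind an explicit call that requires an
  external ECG Q annotation (as does PEP).
- X detection inherits the 0.15·RR search bound; at high heart rates a
  physiologically late X can fall outside the interval and be reported at
  the interval minimum instead.
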