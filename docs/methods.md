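# Model and methods

This note documents the model implemented in `cimodel`, the choices made
where the design was genuinely open, and what the synthetic study
material does and does not establish.

## Signal chain

**Mixing.** Speech and stationary speech-shaped noise are mixed at a
nominal SNR by scaling a randomly chosen noise passage so that
`20·log10(RMS_speech/RMS_noise)` equals the requested value; the speech
itself is never rescaled.  Different repetitions of the protocol use
different noise passages.

**ACE-style coding.** The n-of-m strategy analyses the audio with a
128-sample Hann/FFT front end at 16 kHz, hopping at the per-channel
pulse rate (900 pps → 17.8 samples ≈ 889 frames/s).  The 62 usable FFT
bins between 188 and 7938 Hz are collected into 22 contiguous channels
with boundaries as close to geometric spacing as the bin grid allows
(every channel keeps at least one bin), so low channels are narrow and
high channels wide.  Per frame the 8 largest channel envelopes are kept,
compressed by the logarithmic loudness-growth function
`log(1+ρu)/log(1+ρ)` (ρ = 416.2) between a base level of 1e-3 and a
saturation level of 0.3 (relative to full-scale 1.0 audio), and mapped
onto 100–500 µA.  Selected channels are pulsed once per frame,
interleaved base-to-apex at equal sub-frame offsets so no two pulses
coincide.  Channel 1 (lowest frequencies) stimulates electrode 1, the
most apical contact.  Threshold and comfort currents are global, not
per-electrode.  All of these constants are conventional clinical-style
defaults, declared in `ACEParams` and configurable; the package's
conclusions rest on relative behaviour, not on the exact constants.

**Spatial spread.** The cochlea is a straight 35 mm axis; the 22
contacts (0.75 mm pitch) sit centred on it, and fibers are uniform over
the full length.  Idealized profiles are `exp(-|x-x_e|/λ)` with one λ
for the whole array.  EFI-fitted profiles fit
`v(x) = A·exp(-|x-x_e|/λ) + c` per side of the stimulating contact to
the off-diagonal map entries by bounded nonlinear least squares
(`scipy.optimize.curve_fit`, A ≥ 0, λ > 0, c ≥ 0), initialized by a
log-linear regression of `v - min v` with the offset started at
`min v`.  The contact's own recording is impedance-dominated and
excluded; a linear segment bridges ±0.75 mm around the contact; beyond
the array the fitted exponential (offset clamped at ≥ 0) is
extrapolated.  Edge electrodes with fewer than three recordings on one
side have that side mirrored from the other and are flagged.  FWHM is
the width of the region where the composed profile exceeds half of its
absolute maximum (referenced to 0, offsets included); a side that never
falls below half maximum inside the cochlea is clipped at the boundary
and flagged.  The composed (tent) maximum, not the fitted-curve apex, is
the reference.  Units are stored as kΩ with Ω↔kΩ conversion at I/O; the
absolute unit cancels in the peak-normalized weights used by the model.
Profiles are peak-normalized before driving the nerve model so the
idealized and fitted pathways are commensurable.

**Auditory nerve.** Each fiber is a leaky integrator (τ_m = 0.5 ms,
10 µs steps) of the spread pulse currents (biphasic pulses are rectified
to a 25 µs cathodic-phase drive).  A spike fires when the state crosses
`θ·(1+RS·ξ)·(1+elevation)` with θ = 10 µA, relative spread RS = 0.06 (ξ
redrawn per inter-spike interval, so the single-pulse firing-efficiency
curve is a probit in current with CV ≈ RS), and a relative-refractory
elevation of strength 5 decaying with τ = 1.3 ms after an absolute dead
time drawn per fiber from N(0.7, 0.1²) ms truncated positive.  The
membrane is clamped at rest during the dead time.  Membrane noise (an
OU-like perturbation with stationary SD = RS·θ/3) is injected as
pre-drawn increments every 16 steps with block variance matched to the
stationary SD; this is far finer than the membrane dynamics it perturbs
and keeps the kernel free of per-step random-number calls.  Spike times
are crossing times plus 0.45 ms latency plus 0.1 ms Gaussian jitter;
after jitter, times are re-sorted and nudged so the per-fiber refractory
separation holds exactly.  The distribution families (truncated
normals) are this package's choice; none of the reported behaviour
depends on their fine detail, and all constants are overridable in
`ANParams`.

**Internal representation.** Fibers are pooled into 46 groups: 22
midpoint-bounded electrode groups plus 12 apical and 12 basal 0.75 mm
beyond-array groups; the residual 0.25 mm at each cochlear end is merged
into the terminal groups (merging rather than dropping keeps the
partition exact; either choice yields 46 rows).  Spike counts in 2 ms
frames pass a divisive forward-masking stage — `x' = x/(1 + s·m)` with
`m` the decaying (τ = 100 ms) peak hold of the preceding frame's counts
and s = 0.5 — and are then smoothed by a leaky integrator (τ = 10 ms)
and scaled by a calibrated gain.  The masking mechanism is this
package's construction (the literature names the phenomenon but no
formula).  Two alternatives were implemented and rejected: a subtractive
leaky-average masker is too weak to beat the integrator remnant of a
masker burst 20 ms earlier, and a subtractive peak-hold masker floors
low-count frames at zero and deletes the sustained structure the
recognizer needs.  The divisive form suppresses a probe after recent
activity more strongly than the remnant it rides on, without deleting
information, and satisfies the suppression contract with margin at the
default strength.  Masking precedes smoothing.

**Calibration.** The gain is set per condition so the 99th percentile of
the raw IR amplitudes on ≥ 10 s of clean sentences equals 50, matching
the nominal 0–50 amplitude range (occasional bins exceed 50; the scale
is percentile-pinned, not clipped).  The recognizer is invariant to this
scale; calibration only keeps the representation in its nominal range.

**Internal noise.** Every place-time bin is multiplied by an independent
Gaussian with mean 1 and standard deviation σ_int, without clipping
(negative bins pass through to the recognizer).  Internal noise is
applied to training and test material alike.

**Recognizer.** Whole-word left-to-right HMMs (6 states, one diagonal
Gaussian each) plus a 3-state silence model are trained by embedded
Viterbi training (segmental k-means): flat start by uniform
segmentation, then iterations of forced alignment against the chain
`silence + words + silence` and re-estimation of Gaussians (variances
floored at 1e-3 of the global variance) and self-loop probabilities
(floored at 1e-3).  Five iterations; training is deterministic.
Decoding composes the closed grammar — start silence, the slot
vocabularies in parallel per slot, stop silence — into a single graph
and takes the Viterbi path, which yields exactly one word per slot; word
boundaries are found by the decoder, not supplied.  Features are the raw
46-dimensional IR frames; per-corpus mean/variance normalization is a
no-op for per-state diagonal Gaussians and is therefore not applied.
Ties in decoding resolve to the first-indexed word.  The HMM machinery
is written here (numpy + numba) because embedded training over tied word
models under a fixed grammar is not available in the installed
libraries; `hmmlearn` serves as an independent cross-check in the test
suite.

**SRT extraction.** For every training SNR, models train on the training
repetitions at that SNR and are scored on the held-out repetition at
every test SNR.  The envelope (best training SNR per test SNR) is
scanned from the lowest test SNR upward and the 50% point is linearly
interpolated inside the lowest bracketing pair.  An envelope that never
reaches 50% yields an undefined SRT (flagged, excluded from cohort
correlations); an envelope already at criterion at the grid floor yields
the floor, flagged.

## Synthetic study material

The corpus emulates only what the closed-set protocol needs: a fixed
slot structure (default 5 slots × 10 words), several distinct utterances
per word, and within-word similarity exceeding between-word similarity.
Tokens are harmonic complexes with word-specific fundamental (90–240 Hz)
and two formant-like spectral-envelope trajectories, perturbed per
utterance in pitch (2%), duration (5%) and formant frequencies (3%).
They are not speech: there is no talker variability, no coarticulation,
no consonant structure.  Passing tests therefore demonstrate that the
model chain and protocol behave correctly, not that the absolute SRTs
match human sentence tests.  The noise generator filters white Gaussian
noise to the corpus long-term spectrum (2 dB tolerance is this package's
choice) and RMS-matches it to the corpus.

Synthetic EFI maps follow `A_e·exp(-|x_m-x_e|/λ_e) + c_e` with λ
interpolated from a wider apical to a narrower basal value (matching the
apical-wider trend of measured maps), multiplicative noise of a given
CV, and inflated diagonals so the fitter's exclusion rule is exercised.
Synthetic participant tables draw TRT from N(49, 9²) truncated to
[20, 80], anamnesis fields so the AP score spans roughly −30 to +6 %,
and measured SRT as `7.8 − 0.1·TRT` dB plus 1.5 dB noise, giving a
negative TRT–SRT correlation by construction.

## Individualization arithmetic

Cohort TRT or AP values are mapped linearly onto σ_int ∈ [0.15, 0.25]
with the best performer at 0.15 and the poorest at 0.25 (endpoints
exact); the equal-weight combination is the arithmetic mean of the two
unrounded σ values, which reproduces the published combined column.
Printed-table comparisons round half away from zero at 3 decimals
(0.2105 → 0.211; banker's rounding would fail).  Computing the σ columns
from the printed 1-decimal TRT/AP inputs reproduces the published table
except for four cells that land exactly 0.001 away (participants 32 and
48 AP-only, 63 TRT-only, and the AP-only cohort average) — the source
presumably mapped unrounded metric values.  The linear SRT model is
ordinary least squares with intercept on (mean FWHM, AP, TRT), with the
F-test against the constant model and the fitted-vs-measured Pearson r
attached.  Reproducing the published fitted-vs-measured correlation
requires the per-participant mean FWHMs from the supplementary data
file, which is not part of this repository; only two of the fourteen
values appear in the running text.

## Scaled-down protocol ("desk" preset)

The full published protocol (120 five-word sentences, 12 SNRs from −12
to 21 dB, 8 repetitions, 1000 fibers) is available as the `full`
preset (`full_scale_config`) but is not exercised by the tests.  The `desk` preset — 1 slot ×
10 words, 30 sentences, SNRs −12…3 dB in 3 dB steps, 3 repetitions
(2 train / 1 test), 100 fibers — runs a full (λ, σ_int) cell in well
under a minute on one CPU and is the problem size used for all
stochastic acceptance checks.  Sweep replications ("seeds") resample the
sentence plan, noise passages, nerve stochasticity and internal noise
together; stages that do not depend on the varied parameter are cached
(electrodograms across λ and σ, pre-noise IRs across σ), which also acts
as common random numbers for the comparisons.  At this scale the model
separates λ = 3 mm clearly from λ = 9 and 15 mm, while the 9 → 15 mm
step is small relative to the per-cell score noise (about 30 words per
matrix cell); with the resampled replications the 3-seed medians are
monotone in both λ and σ_int.  Conditions at wide spread and strong
internal noise often never reach 50% intelligibility on the desk grid
and are reported undefined — the same behaviour the full-scale model
shows for its poorest-performing listener — and are ranked worse than
any numeric SRT in trend checks.  The published test-retest spread
(0.4 dB) is a full-scale quantity; at desk scale only the reporting
mechanism is checked.

## Known limitations

- Absolute desk-scale SRTs are not comparable to human matrix-test SRTs
  (easier task: 1 slot, synthetic tokens, 10 alternatives).
- T/C levels, loudness growth and electrode-nerve distance are global,
  not individualized; no spiral-ganglion status, no 3-D volume
  conduction.
- The LIF parameter values are conventional electric-stimulation
  figures, not fits to physiological data.
- The forward-masking stage is phenomenological; its constants (100 ms,
  strength 0.5) are defaults, and only its suppression contract is
  load-bearing.
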