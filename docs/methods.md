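# Methods

## The detection problem

Horizontal EOG measures gaze via the corneo-retinal potential, an
uncalibrated voltage, so all amplitudes in this package are arbitrary
units and every decision rule is amplitude-invariant. Nystagmus appears
as a sawtooth: a slow drift phase followed by a fast corrective phase.
Under the convention *positive amplitude = rightward gaze*, a
right-beating episode (fast phase rightward) has a negative-velocity slow
phase; left-beating is the mirror image. The task is day-level: decide
for each calendar day of recording whether it contains at least one
episode, and type the episodes found.

## Synthetic data generator (`eog_synth`)

No ambulatory EOG recordings of this kind are publicly deposited, so the
generator emulates them. A day is the sum of independent seeded
components:

| component | model | default |
|---|---|---|
| nystagmus episodes | piecewise-linear sawtooth, slow:fast ratio 0.8, peak-to-peak amplitude 1.0, 30 s | per schedule |
| baseline drift | Gaussian random walk | 0.05 units/√s |
| saccades | Poisson step process, uniform magnitude, random sign | 0.5 /s, 0.3–1.5 units |
| sensor noise | white Gaussian | σ = 0.15 |
| locomotion artifact | sinusoidal burst (off by default) | — |
| marker artifact | Gaussian impulse (off by default) | — |

The sampling rate of 41.5 Hz is implied by the analysis geometry (500-sample
window with 0.083 Hz bin spacing ⇒ fs = 0.083 × 500). Episode frequencies
are restricted to the three stimulus classes 0.8 / 1.0 / 1.2 Hz. Event
amplitude 1.0 against noise σ 0.15 makes the frame SNR comfortable in the
spectral domain but leaves the raw velocity sign noise-dominated, which is
what makes the typing step non-trivial. All outputs are pure functions of
(config, calendar date, participant id): the per-day RNG stream is derived
from the seed plus a CRC of date and id.

What the generator does **not** emulate: blink/EMG biophysics, electrode
impedance changes, diurnal drift of the corneo-retinal potential, device
dropout, clock drift. Passing the synthetic replication therefore shows
the pipeline's logic is sound at a realistic SNR, not that it would reach
the same figures on real recordings.

"Noise-free" in tests means the white-noise source is off; drift and
saccades (background eye movement) remain unless stated.

## Frame features (`features`)

Sliding 500-sample windows, 80 % overlap (hop 100), trailing partial
window discarded. Each window is mean-removed (offset invariance), FFT'd
without a taper — the sawtooth's harmonic comb is sharpest untapered, and
a Hann taper is available as an option — and the single-sided amplitudes
2|X_k|/N are retained for bins whose frequency lies in 0.25–7 Hz. Band
edges map to the *nearest* bin index, inclusive: at fs 41.5 this keeps
k = 3…84, i.e. 82 bins, which is the only reading that makes the window
length, band, bin spacing and bin count mutually consistent.

## Detector (`detector`)

**Ensemble.** SVC (RBF, C = 1, γ = 1/n_features), linear discriminant
analysis, and gradient-boosted trees (100 rounds, depth 3), all on
standardised features, majority vote of the three (ties impossible).
Frames are labelled positive for training iff ≥ 50 % of the window
overlaps a ground-truth episode; background frames are downsampled to
5 : 1 against positives (seeded). Hyperparameters are deliberately plain —
the features, not the classifiers, carry the discrimination.

**Sieve.** Closing (fill interior zero-gaps ≤ max_gap = 2) then opening
(drop positive runs < min_run = 3). The operation is idempotent and is
tested against an exhaustive position-by-position oracle on all binary
strings up to length 12. A 30 s episode spans ≈ 8–13 positive frames at
the default geometry, so genuine events survive opening comfortably.

**DP sawtooth validation.** Each candidate run is first screened
(duration ≥ 10 s; modal spectral bin, searched over 0.25–7 Hz, inside the
0.5–2 Hz event band — this is what rejects locomotion-like periodic
artifacts at other rates), then scored: the segment is detrended by
subtracting a 63-sample (≈ 1.5 s, ≥ one beat period) running median —
removing saccadic baseline jumps and drift while preserving the beat
waveform — smoothed with a 5-sample moving average, z-normalised, and
aligned with a z-normalised ideal sawtooth at the candidate frequency by
dynamic time warping under a Sakoe–Chiba band of 10 % of the length, with
local cost |x−y| and total cost normalised by the maximal path length
n+m−1. The score is computed against both beat polarities and the
smaller kept, making it direction-invariant. Acceptance threshold 0.18:
on a calibration set of 48 noisy synthetic events and 24 background
segments (default generator settings), event scores fell at or below
0.150 and background scores at or above 0.209, and 0.18 is the midpoint
of the gap. With the degenerate single-point template and a full band the
score reduces to mean absolute deviation from a constant, which pins the
normalisation convention.

**Smoothing choice.** The 5-sample moving average (~0.12 s at 41.5 Hz)
used before velocity-sign analysis and DTW is set by waveform geometry:
the fast phase of the fastest class lasts (1−0.8)/1.2 ≈ 0.17 s ≈ 7
samples, so a 5-sample average suppresses sample-to-sample noise without
erasing the fast phase.

## Event typing (`event_typing`)

**Direction.** Velocity = first difference of the smoothed event signal.
Each frame's weight is (n_pos − n_neg)/(n_pos + n_neg) over velocity
signs (zeros excluded; bounded in [−1, 1]); the mean over frames decides:
negative ⇒ right-beating, positive ⇒ left-beating, exact zero ties to
right (documented, arbitrary). A sinusoidal segment yields |weight| ≈ 0 —
no directional confidence — which is correct behaviour, not a failure.

**Frequency.** Amplitude spectrum of the whole event span (no
zero-padding), modal bin searched in 0.5–2 Hz, assigned to the nearest
class in absolute Hz; class-distance ties go to the lower class.
Amplitude ties between bins are resolved by the larger adjacent-bin
amplitude (reading "highest neighbouring bin" as highest-amplitude; a
frequency-neighbour reading would be the only alternative and is noted in
the code).

## Trial management (`dayio`) and statistics (`dxstats`)

Re-segmentation partitions continuous records by calendar date, taking
device timestamps at face value (no drift or daylight-saving correction —
no correction procedure is defined for this data). Same-date records are
concatenated with the gap logged, never interpolated. The trial's two
boundary half-days merge into one pseudo-day with the seam recorded.
Blinding assigns shuffled opaque names and emits a coding sheet; the
blinded copies carry no ground truth or markers.

Sensitivity/specificity use the conventional TP/(TP+FN), TN/(TN+FP)
definitions with exact Clopper–Pearson intervals (the interval choice is
fixed by the requirement that 111/112 gives 95.13–99.98 %; Wilson is
available as an alternative). Sample-size planning uses
n = ⌈z² p(1−p)/d²⌉, which gives 84 at (p = 0.98, d = 0.03, 95 %); planning
texts that round the z-quantile or add a continuity correction can give
85, and the function warns when the margin is not small relative to
p(1−p), as is the case for that plan.

## Problem sizes and determinism

The blinded replication used by the tests and by `scripts/acceptance.py`
runs 120 half-hour pseudo-days (40 positive, stimuli cycled uniformly
over the six class × direction combinations) against an ensemble trained
on 48 disjoint five-minute days — about 4 500 day-level frame
classifications and ~40 DTW validations, a couple of minutes of CPU at
most. Full 23-hour days are supported by the same code paths. Every
random choice flows from an explicit seed; identical seeds give
byte-identical signals and identical models.

## Known limitations

- Slow-phase velocity in degrees/s — the clinical intensity measure —
  requires angular calibration of the corneo-retinal potential and is out
  of scope; only the beat frequency and direction are reported.
- The DP score accepts *any* sufficiently periodic in-band waveform shape
  close to a sawtooth after warping; strongly periodic artifacts inside
  0.5–2 Hz (e.g. rhythmic locomotion crosstalk at ~1 Hz) can pass it, as
  they did in the ambulatory trial this design follows.
- The direction rule assumes the positive-equals-rightward electrode
  polarity; for real data with the opposite montage the labels flip
  (config-exposed convention).
- Only the horizontal channel is modelled; vertical/torsional nystagmus
  is invisible to the pipeline.
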