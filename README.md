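# nystagdet

Detection and typing of short nystagmus episodes in day-scale ambulatory
electro-oculography (EOG) recordings.

Dizziness caused by inner-ear (vestibular) disease is episodic: by the time
a patient reaches a clinic, the attack — and the involuntary sawtooth eye
movement (*nystagmus*) that accompanies it — is usually over. Wearable EOG
monitors record horizontal eye position continuously for days, and the
analysis problem becomes finding a ~30-second sawtooth episode inside many
hours of ordinary eye movement, then reporting which way it beats and how
fast. `nystagdet` implements an offline detection pipeline for this
problem, a seeded synthetic-trial generator to evaluate it against, and the
diagnostic-accuracy statistics used to score a blinded detection trial.

## Method

A day of signal (sampling rate 41.5 Hz) is processed as follows:

1. **Frame features** — a sliding 500-sample window with 80 % overlap
   (hop 100); each window is mean-removed and FFT'd, and the 82 amplitude
   bins between 0.25 and 7 Hz (spacing fs/500 = 0.083 Hz) form the frame's
   feature vector.
2. **Ensemble classification** — three classifiers (RBF support-vector
   machine, linear discriminant, 100-round depth-3 boosted trees) vote on
   every frame; the majority of the three is the frame label.
3. **Sieve smoothing** — morphological closing then opening on the binary
   label sequence (fill gaps ≤ 2 frames, drop runs < 3 frames).
4. **Candidate validation** — each remaining run of positive frames is
   checked: duration ≥ 10 s, modal spectral bin inside the 0.5–2 Hz event
   band, and a dynamic-programming sawtooth match. For the last step the
   segment is median-detrended, smoothed, z-normalised and aligned by
   banded dynamic time warping (Sakoe–Chiba band, 10 % of length) against
   an ideal sawtooth at the candidate frequency; the alignment cost per
   path step must fall below a calibrated threshold (0.18).
5. **Event typing** — beat direction from the sign balance of the
   smoothed velocity signal, averaged over frames (slow phases of a
   right-beating sawtooth carry negative velocity, so a negative mean
   weight ⇒ right-beating); beat frequency from the modal FFT bin of the
   whole event, assigned to the nearest class in {0.8, 1.0, 1.2} Hz.
6. **Evaluation** — a day counts as positive iff it contains an accepted
   event. Sensitivity TP/(TP+FN) and specificity TN/(TN+FP) are reported
   with exact (Clopper–Pearson) binomial 95 % confidence intervals,
   `lower = B⁻¹(α/2; x, n−x+1)`, `upper = B⁻¹(1−α/2; x+1, n−x)`.

Because no ambulatory EOG trial data is publicly deposited, the package
includes a generator (`eog_synth`) that emulates the recording: sawtooth
episodes (slow:fast phase ratio 0.8) on top of baseline drift, Poisson
saccades, Gaussian sensor noise, and optional periodic or impulsive
artifacts, all deterministic given a seed. `dayio` reproduces the trial's
data handling: calendar-day re-segmentation, half-day merging, and
blinding behind randomised filenames with a coding sheet.

## Worked example

```python
from nystagdet import run_blinded_replication

rep = run_blinded_replication(seed=1, n_days=24, n_positive=8,
                              day_length=600.0,
                              n_train_positive=12, n_train_negative=12)
print(rep["detection"]["confusion"].counts)
print(rep["detection"]["accuracy"].summary())
```

prints

```
[[ 8  0]
 [ 0 16]]
sensitivity 100.0% (95% CI: 63.06% to 100.00%), specificity 100.0% (95% CI: 79.41% to 100.00%)
```

i.e. on a 24-day blinded synthetic trial (8 days holding one 30 s episode,
10-minute days) every positive day was detected and no background day
raised a false alarm; the wide intervals reflect the small day counts.

The same workflow is available from the shell:

```sh
nystagdet simulate --out train/ --seed 3 --n-days 16 --n-positive 8
nystagdet simulate --out eval/  --seed 4 --n-days 12 --n-positive 4
nystagdet blind   --data eval/  --out blinded/ --seed 5
nystagdet train   --data train/ --out model.joblib
nystagdet detect  --model model.joblib --data blinded/ --out detections.json
nystagdet unblind-evaluate --detections detections.json \
    --coding-sheet blinded/coding_sheet.csv --out report.json
```

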