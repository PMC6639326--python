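"""Frame-level nystagmus detection.

Pipeline: three frame classifiers (an RBF support-vector machine, a linear
discriminant, and a boosted-tree ensemble) vote on every FFT frame; the
majority label sequence is smoothed with a morphological sieve filter;
maximal runs of positive frames become candidate events; each candidate is
validated by a dynamic-programming (banded DTW) comparison of its waveform
against an ideal sawtooth at the candidate's modal frequency, with two
heuristic pre-filters (minimum duration, modal bin inside the event band).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import TYPE_CHECKING, Optional, Sequence

import joblib
import numpy as np
from numba import njit
from scipy.ndimage import median_filter
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .event_typing import DEFAULT_SMOOTH_WINDOW, _smooth, modal_frequency
from .features import FrameFeatureMatrix, FrameSpec

if TYPE_CHECKING:  # pragma: no cover
    from .eog_synth import EogDay


@dataclass(frozen=True)
class DetectorConfig:
    """Post-classification smoothing and validation parameters.

    A 30 s event spans roughly 8-13 positive frames at the default frame
    spec, so min_run=3 / max_gap=2 removes isolated false frames without
    threatening genuine events.  The DP acceptance threshold sits midway
    between the score ranges of noisy synthetic events and of background
    segments, calibrated on synthetic validation days (see docs/methods.md).
    """

    min_run: int = 3
    max_gap: int = 2
    dp_threshold: float = 0.18
    min_event_s: float = 10.0
    event_band: tuple[float, float] = (0.5, 2.0)
    search_band: tuple[float, float] = (0.25, 7.0)  # modal-bin search range
    slow_fast_ratio: float = 0.8
    band_fraction: float = 0.10
    smooth_window: int = DEFAULT_SMOOTH_WINDOW
    detrend_window: int = 63  # ~1.5 s: running-median baseline removal
    use_duration_prefilter: bool = True
    use_band_prefilter: bool = True


@dataclass(frozen=True)
class EnsembleHyperparams:
    """Hyperparameters of the three ensemble members (all config-exposed)."""

    svm_c: float = 1.0
    svm_gamma: str | float = "auto"  # 1/n_features
    boost_rounds: int = 100
    boost_depth: int = 3
    background_ratio: float = 5.0  # background:nystagmus downsampling ratio


@dataclass
class FrameLabelSequence:
    """Per-frame binary labels with the underlying member vote counts."""

    labels: np.ndarray  # 0/1 per frame
    votes: np.ndarray  # 0..3 per frame
    frame_times: np.ndarray  # window start times, s

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.int8)
        self.votes = np.asarray(self.votes, dtype=np.int8)
        if not (len(self.labels) == len(self.votes) == len(self.frame_times)):
            raise ValueError("labels, votes and frame_times must align")


@dataclass
class CandidateRun:
    """A maximal run of positive frames, before/after DP validation."""

    start_frame: int
    end_frame: int  # inclusive
    start_s: float
    end_s: float
    dp_score: Optional[float] = None
    modal_frequency: Optional[float] = None
    accepted: bool = False

    def __post_init__(self):
        if self.end_frame < self.start_frame:
            raise ValueError("run end must not precede its start")


@dataclass
class EnsembleModel:
    """Three trained frame classifiers plus the shared feature scaler."""

    scaler: StandardScaler
    svm: SVC
    lda: LinearDiscriminantAnalysis
    boost: GradientBoostingClassifier
    feature_hash: str
    n_features: int
    class_balance: tuple[int, int]
    hyperparams: EnsembleHyperparams
    seed: int

    @property
    def members(self):
        return {"svm": self.svm, "lda": self.lda, "boost": self.boost}

    def save(self, path) -> None:
        joblib.dump(self, path)

    @staticmethod
    def load(path) -> "EnsembleModel":
        model = joblib.load(path)
        if not isinstance(model, EnsembleModel):
            raise TypeError(f"{path} does not contain an EnsembleModel")
        return model


def feature_space_hash(features: FrameFeatureMatrix) -> str:
    """Stable fingerprint of the feature geometry (bin frequencies + spec)."""
    h = hashlib.sha256()
    h.update(np.round(features.bin_frequencies, 6).tobytes())
    h.update(str(features.spec.window_length).encode())
    h.update(str(features.spec.overlap_fraction).encode())
    return h.hexdigest()[:16]


# ---------------------------------------------------------------------------
# training


def frame_labels(day: "EogDay", spec: FrameSpec = FrameSpec()) -> np.ndarray:
    """Ground-truth binary label per frame.

    A frame is positive iff at least half of its window overlaps a
    ground-truth nystagmus event.
    """
    from .features import frame_signal

    _, starts = frame_signal(day, spec)
    win_s = spec.window_duration_s(day.sampling_rate)
    labels = np.zeros(len(starts), dtype=np.int8)
    for ev in day.ground_truth or []:
        overlap = np.minimum(starts + win_s, ev.end_s) - np.maximum(
            starts, ev.start_s
        )
        labels[overlap >= 0.5 * win_s] = 1
    return labels


def train_ensemble(
    features: Sequence[FrameFeatureMatrix],
    labels: Sequence[np.ndarray],
    hyperparams: EnsembleHyperparams = EnsembleHyperparams(),
    seed: int = 0,
) -> EnsembleModel:
    """Train the three-member frame-classification ensemble.

    Background frames are downsampled (seeded) to ``background_ratio`` times
    the nystagmus frame count to limit class imbalance.  Training is
    deterministic given (inputs, hyperparams, seed).
    """
    if isinstance(features, FrameFeatureMatrix):
        features = [features]
        labels = [labels]
    X = np.vstack([f.values for f in features])
    y = np.concatenate([np.asarray(l, dtype=int) for l in labels])
    if len(X) != len(y):
        raise ValueError("features and labels must align frame-for-frame")
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError(
            "training data must contain both nystagmus and background frames"
        )
    hashes = {feature_space_hash(f) for f in features}
    if len(hashes) != 1:
        raise ValueError("all training feature matrices must share one feature space")

    rng = np.random.default_rng(seed)
    pos = np.flatnonzero(y == 1)
    neg = np.flatnonzero(y == 0)
    max_neg = int(round(hyperparams.background_ratio * len(pos)))
    if len(neg) > max_neg > 0:
        neg = rng.choice(neg, max_neg, replace=False)
    keep = np.sort(np.concatenate([pos, neg]))
    X, y = X[keep], y[keep]

    scaler = StandardScaler().fit(X)
    Xs = scaler.transform(X)
    svm = SVC(C=hyperparams.svm_c, kernel="rbf", gamma=hyperparams.svm_gamma)
    lda = LinearDiscriminantAnalysis()
    boost = GradientBoostingClassifier(
        n_estimators=hyperparams.boost_rounds,
        max_depth=hyperparams.boost_depth,
        random_state=seed,
    )
    svm.fit(Xs, y)
    lda.fit(Xs, y)
    boost.fit(Xs, y)
    return EnsembleModel(
        scaler=scaler,
        svm=svm,
        lda=lda,
        boost=boost,
        feature_hash=hashes.pop(),
        n_features=X.shape[1],
        class_balance=(int(np.sum(y == 1)), int(np.sum(y == 0))),
        hyperparams=hyperparams,
        seed=seed,
    )


def classify_frames(
    model: EnsembleModel, features: FrameFeatureMatrix
) -> FrameLabelSequence:
    """Majority vote of the three members on every frame."""
    if features.n_bins != model.n_features:
        raise ValueError(
            f"feature dimension {features.n_bins} does not match the model "
            f"({model.n_features})"
        )
    if feature_space_hash(features) != model.feature_hash:
        raise ValueError(
            "feature space (bin frequencies / frame spec) does not match the "
            "one the model was trained on"
        )
    Xs = model.scaler.transform(features.values)
    votes = sum(m.predict(Xs).astype(np.int8) for m in model.members.values())
    labels = (votes >= 2).astype(np.int8)
    return FrameLabelSequence(labels, votes, features.frame_start_times)


# ---------------------------------------------------------------------------
# sieve smoothing and run extraction


def _runs_of(x: np.ndarray, value: int):
    """(start, end_inclusive) pairs of maximal runs of ``value``."""
    idx = np.flatnonzero(np.asarray(x) == value)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate([[idx[0]], idx[breaks + 1]])
    ends = np.concatenate([idx[breaks], [idx[-1]]])
    return list(zip(starts.tolist(), ends.tolist()))


def sieve_filter(labels, min_run: int = 3, max_gap: int = 2):
    """Morphological sieve smoothing of a binary label sequence.

    Closing then opening: interior zero-gaps of length <= ``max_gap`` that
    are flanked by positive frames are filled, then positive runs shorter
    than ``min_run`` frames are removed.  Idempotent.

    Accepts either a plain binary array or a FrameLabelSequence (in which
    case a new FrameLabelSequence with smoothed labels is returned).
    """
    if min_run < 1:
        raise ValueError("min_run must be >= 1")
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    if isinstance(labels, FrameLabelSequence):
        smoothed = sieve_filter(labels.labels, min_run, max_gap)
        return FrameLabelSequence(smoothed, labels.votes, labels.frame_times)
    x = np.asarray(labels, dtype=np.int8).copy()
    n = len(x)
    # closing: fill short interior gaps
    for s, e in _runs_of(x, 0):
        if s > 0 and e < n - 1 and (e - s + 1) <= max_gap:
            x[s : e + 1] = 1
    # opening: drop short positive runs
    for s, e in _runs_of(x, 1):
        if (e - s + 1) < min_run:
            x[s : e + 1] = 0
    return x


def extract_runs(
    labels: FrameLabelSequence,
    spec: FrameSpec = FrameSpec(),
    sampling_rate: float = 41.5,
) -> list[CandidateRun]:
    """Maximal positive runs as candidate events.

    A run's end time is the last frame's start time plus the window
    duration, i.e. the span of signal its frames cover.
    """
    win_s = spec.window_duration_s(sampling_rate)
    runs = []
    for s, e in _runs_of(labels.labels, 1):
        runs.append(
            CandidateRun(
                start_frame=int(s),
                end_frame=int(e),
                start_s=float(labels.frame_times[s]),
                end_s=float(labels.frame_times[e] + win_s),
            )
        )
    return runs


# ---------------------------------------------------------------------------
# DP sawtooth validation


@njit(cache=False)
def _banded_dtw(x, y, band):  # pragma: no cover - exercised via wrapper
    n, m = len(x), len(y)
    INF = 1e30
    prev = np.full(m + 1, INF)
    curr = np.full(m + 1, INF)
    prev[0] = 0.0
    for i in range(1, n + 1):
        lo = max(1, i * m // n - band)
        hi = min(m, i * m // n + band)
        curr[:] = INF
        for j in range(lo, hi + 1):
            c = abs(x[i - 1] - y[j - 1])
            best = prev[j - 1]
            if prev[j] < best:
                best = prev[j]
            if curr[j - 1] < best:
                best = curr[j - 1]
            curr[j] = c + best
        prev, curr = curr, prev
    return prev[m]


def dtw_score(x: np.ndarray, y: np.ndarray, band_fraction: float = 0.10) -> float:
    """Banded DTW alignment cost per path step between two sequences.

    Local cost |x_i - y_j|; Sakoe-Chiba band of half-width
    ``band_fraction * max(n, m)`` around the diagonal; the total cost is
    normalised by the maximal path length n + m - 1.  0 for identical
    sequences; >= 0 always.
    """
    x = np.ascontiguousarray(x, dtype=np.float64)
    y = np.ascontiguousarray(y, dtype=np.float64)
    if len(x) < 1 or len(y) < 1:
        raise ValueError("sequences must be non-empty")
    band = max(1, int(np.ceil(band_fraction * max(len(x), len(y)))))
    total = _banded_dtw(x, y, band)
    return float(total / (len(x) + len(y) - 1))


def _znorm(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        return x - x.mean()
    return (x - x.mean()) / sd


def dp_sawtooth_score(
    segment: Sequence[float],
    candidate_frequency: float,
    sampling_rate: float,
    slow_fast_ratio: float = 0.8,
    band_fraction: float = 0.10,
    smooth_window: int = DEFAULT_SMOOTH_WINDOW,
    detrend_window: int = 63,
) -> float:
    """How well a segment matches an ideal sawtooth at the candidate frequency.

    The segment is detrended with a running-median baseline (window
    ``detrend_window`` samples, >= one beat period, so gaze shifts and
    slow drift are removed while the beat waveform is preserved), lightly
    smoothed and z-normalised; a z-normalised sawtooth template of equal
    duration is constructed at the candidate frequency and the banded-DTW
    cost per path step is returned (lower = better; 0 for an exact
    template without detrending).  The score is evaluated against both
    beat polarities and the smaller cost is kept, so it is direction- and
    amplitude-invariant.
    """
    from .eog_synth import sawtooth_event

    x = np.asarray(segment, dtype=float)
    if candidate_frequency <= 0:
        raise ValueError("candidate_frequency must be positive")
    if len(x) < 2 * sampling_rate / candidate_frequency:
        raise ValueError(
            "segment must cover at least 2 periods of the candidate frequency"
        )
    if detrend_window > 1:
        x = x - median_filter(x, size=detrend_window, mode="nearest")
    xs = _znorm(_smooth(x, smooth_window))
    template = _znorm(
        sawtooth_event(
            candidate_frequency,
            len(x) / sampling_rate,
            "right",
            1.0,
            slow_fast_ratio,
            sampling_rate,
        )
    )
    if len(template) != len(xs):  # rounding guard
        template = template[: len(xs)]
    return min(
        dtw_score(xs, template, band_fraction),
        dtw_score(-xs, template, band_fraction),
    )


def validate_runs(
    runs: Sequence[CandidateRun],
    day: "EogDay",
    config: DetectorConfig = DetectorConfig(),
) -> list[CandidateRun]:
    """Accept or reject candidate runs.

    Heuristic pre-filters first: minimum duration and modal-bin frequency
    inside the event band.  Survivors are accepted iff their DP sawtooth
    score at the modal frequency is at or below the threshold.
    """
    out = []
    for run in runs:
        run = CandidateRun(**vars(run))
        start_s = max(0.0, run.start_s)
        end_s = min(day.duration_s, run.end_s)
        i0 = int(round(start_s * day.sampling_rate))
        i1 = int(round(end_s * day.sampling_rate))
        seg = np.asarray(day.samples[i0:i1], dtype=float)
        if config.use_duration_prefilter and (end_s - start_s) < config.min_event_s:
            out.append(run)
            continue
        if config.detrend_window > 1 and len(seg) > config.detrend_window:
            # remove gaze-shift/drift baseline so the modal-bin search and
            # the DP score see the beat waveform, not the baseline
            seg = seg - median_filter(seg, size=config.detrend_window, mode="nearest")
        try:
            f_modal = modal_frequency(seg, day.sampling_rate, config.search_band)
        except ValueError:
            out.append(run)
            continue
        run.modal_frequency = f_modal
        if config.use_band_prefilter and not (
            config.event_band[0] <= f_modal <= config.event_band[1]
        ):
            out.append(run)
            continue
        try:
            score = dp_sawtooth_score(
                seg,
                f_modal,
                day.sampling_rate,
                config.slow_fast_ratio,
                config.band_fraction,
                config.smooth_window,
                detrend_window=1,  # segment already detrended above
            )
        except ValueError:
            out.append(run)
            continue
        run.dp_score = score
        run.accepted = score <= config.dp_threshold
        out.append(run)
    return out


def detect_day(
    model: EnsembleModel,
    day: "EogDay",
    spec: FrameSpec = FrameSpec(),
    config: DetectorConfig = DetectorConfig(),
) -> list[CandidateRun]:
    """Full detection chain for one day: features -> votes -> sieve ->
    runs -> DP validation.  Returns all candidate runs with accepted flags."""
    from .features import day_features

    feats = day_features(day, spec)
    seq = classify_frames(model, feats)
    seq = sieve_filter(seq, config.min_run, config.max_gap)
    runs = extract_runs(seq, spec, day.sampling_rate)
    return validate_runs(runs, day, config)
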