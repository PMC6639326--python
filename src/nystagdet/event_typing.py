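"""Beat-direction and beat-frequency classification of nystagmus events.

Direction: the velocity (first difference) of a right-beating sawtooth is
negative for most of each beat (the slow phase occupies most of the period
and drifts leftward under the rightward-positive convention).  Each frame
of the event is given a weight in [-1, 1] — the signed excess of positive
over negative velocity samples — and the event's mean weight decides the
direction: negative mean => right-beating, positive => left-beating.

Frequency: the amplitude spectrum of the whole event is searched within the
0.5-2.0 Hz event band; the modal (arg-max) bin's frequency is assigned to
the nearest class in {0.8, 1.0, 1.2} Hz.  Amplitude ties between bins are
broken by the larger adjacent-bin amplitude; class-distance ties go to the
lower class.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import TYPE_CHECKING, Optional, Sequence

import numpy as np
import scipy.fft
from scipy.ndimage import uniform_filter1d

if TYPE_CHECKING:  # pragma: no cover
    from .eog_synth import EogDay
    from .features import FrameSpec

EVENT_BAND = (0.5, 2.0)
"""Hz; the band searched for the modal frequency bin of an event."""

DEFAULT_SMOOTH_WINDOW = 5
"""Samples of moving-average smoothing applied before velocity analysis.
At 41.5 Hz this is ~0.12 s — short enough to preserve the fast phase
(>= ~0.17 s for the stimulus classes) while suppressing sample-to-sample
sensor noise that would otherwise randomise velocity signs."""


@dataclass
class NystagmusEvent:
    """A detected (or ground-truth) nystagmus episode."""

    start_s: float
    end_s: float
    direction: Optional[str] = None
    direction_weight: Optional[float] = None
    frequency_class: Optional[float] = None
    modal_bin_frequency: Optional[float] = None
    dp_score: Optional[float] = None

    def __post_init__(self):
        if self.end_s <= self.start_s:
            raise ValueError("event end must follow its start")
        if self.direction_weight is not None and not (
            -1.0 <= self.direction_weight <= 1.0
        ):
            raise ValueError("direction_weight must lie in [-1, 1]")

    @property
    def span(self) -> tuple[float, float]:
        return (self.start_s, self.end_s)

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    def overlaps(self, other: "NystagmusEvent") -> bool:
        return self.start_s < other.end_s and other.start_s < self.end_s

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "NystagmusEvent":
        return cls(**d)


def _smooth(x: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return np.asarray(x, dtype=float)
    return uniform_filter1d(np.asarray(x, dtype=float), window, mode="nearest")


def direction_weight(segment: Sequence[float]) -> float:
    """Signed proportion of positive vs negative velocities, in [-1, 1].

    weight = (n_pos - n_neg) / (n_pos + n_neg) over the first differences,
    zero velocities excluded; 0 when every velocity is zero.
    """
    x = np.asarray(segment, dtype=float)
    if x.size < 2:
        raise ValueError("segment must contain at least 2 samples")
    v = np.diff(x)
    n_pos = int(np.sum(v > 0))
    n_neg = int(np.sum(v < 0))
    if n_pos + n_neg == 0:
        return 0.0
    return (n_pos - n_neg) / (n_pos + n_neg)


def _span_slice(day: "EogDay", span: tuple[float, float]) -> np.ndarray:
    start_s, end_s = span
    if start_s < 0 or end_s > day.duration_s + 1.0 / day.sampling_rate:
        raise ValueError(
            f"span [{start_s}, {end_s}] s outside day [0, {day.duration_s}] s"
        )
    i0 = int(round(start_s * day.sampling_rate))
    i1 = min(day.n_samples, int(round(end_s * day.sampling_rate)))
    return np.asarray(day.samples[i0:i1], dtype=float)


def classify_direction(
    day: "EogDay",
    span: tuple[float, float],
    frame_spec: Optional["FrameSpec"] = None,
    smooth_window: int = DEFAULT_SMOOTH_WINDOW,
) -> tuple[str, float]:
    """Beat direction of the event at ``span``: ('left'|'right', mean weight).

    The event is lightly smoothed, cut into the same sliding windows the
    detector uses, and the per-frame direction weights are averaged.  Mean
    weight < 0 => right-beating (slow phase dominates the sample count and
    is negative-velocity for right-beating); > 0 => left-beating; an exact
    0 ties to right.
    """
    from .features import FrameSpec

    if frame_spec is None:
        frame_spec = FrameSpec()
    seg = _smooth(_span_slice(day, span), smooth_window)
    w, hop = frame_spec.window_length, frame_spec.hop
    if len(seg) < 2:
        raise ValueError("event span too short for direction analysis")
    if len(seg) < w:
        weights = [direction_weight(seg)]
    else:
        n_frames = (len(seg) - w) // hop + 1
        weights = [
            direction_weight(seg[i * hop : i * hop + w]) for i in range(n_frames)
        ]
    mean_w = float(np.mean(weights))
    label = "left" if mean_w > 0 else "right"
    return label, mean_w


def modal_frequency(
    segment: Sequence[float],
    sampling_rate: float,
    band: tuple[float, float] = EVENT_BAND,
    pad_factor: int = 1,
    tie_break: str = "amplitude",
) -> float:
    """Frequency (Hz) of the modal amplitude-spectrum bin within ``band``.

    The segment is mean-removed and FFT'd at ``pad_factor`` times its
    length (1 = no zero-padding; larger values place bins more finely).
    Amplitude ties between bins are resolved by comparing each tied bin's
    largest adjacent-bin amplitude and keeping the tied bin with the
    greater neighbour (``tie_break='amplitude'``); ``tie_break='frequency'``
    instead keeps the highest-frequency tied bin.
    """
    x = np.asarray(segment, dtype=float)
    if x.size < 4:
        raise ValueError("segment too short for spectral analysis")
    if pad_factor < 1:
        raise ValueError("pad_factor must be >= 1")
    n = pad_factor * x.size
    amp = np.abs(scipy.fft.rfft(x - x.mean(), n=n))
    freqs = np.arange(amp.size) * sampling_rate / n
    in_band = np.flatnonzero((freqs >= band[0]) & (freqs <= band[1]))
    if in_band.size == 0:
        raise ValueError(
            f"no FFT bins inside the event band {band} Hz for a segment of "
            f"{x.size} samples at {sampling_rate} Hz"
        )
    band_amp = amp[in_band]
    peak = band_amp.max()
    tied = in_band[np.isclose(band_amp, peak, rtol=1e-9, atol=0.0)]
    if tied.size > 1 and tie_break == "frequency":
        best = int(tied[-1])
    elif tied.size > 1:
        # tie-break: the tied bin whose larger neighbour is greatest wins
        def neighbour_amp(k: int) -> float:
            cands = [amp[k - 1]] if k - 1 >= 0 else []
            if k + 1 < amp.size:
                cands.append(amp[k + 1])
            return max(cands) if cands else 0.0

        best = max(tied, key=lambda k: (neighbour_amp(k), -k))
    else:
        best = int(tied[0])
    return float(freqs[best])


def nearest_class(frequency: float, classes: Sequence[float]) -> float:
    """Nearest class centre in absolute Hz; distance ties go to the lower class."""
    ordered = sorted(classes)
    return min(ordered, key=lambda c: (abs(c - frequency), c))


def classify_frequency(
    day: "EogDay",
    span: tuple[float, float],
    classes: Sequence[float] = (0.8, 1.0, 1.2),
    band: tuple[float, float] = EVENT_BAND,
) -> tuple[float, float]:
    """Frequency class of the event at ``span``: (class Hz, modal bin Hz)."""
    seg = _span_slice(day, span)
    min_class = min(classes)
    if len(seg) / day.sampling_rate < 2.0 / min_class:
        raise ValueError(
            f"event span must cover at least 2 periods of the lowest class "
            f"({min_class} Hz)"
        )
    f_modal = modal_frequency(seg, day.sampling_rate, band)
    return nearest_class(f_modal, classes), f_modal


def type_event(
    day: "EogDay",
    span: tuple[float, float],
    classes: Sequence[float] = (0.8, 1.0, 1.2),
    frame_spec: Optional["FrameSpec"] = None,
    dp_score: Optional[float] = None,
) -> NystagmusEvent:
    """Full typing (direction + frequency) of one accepted event span."""
    direction, weight = classify_direction(day, span, frame_spec)
    fclass, f_modal = classify_frequency(day, span, classes)
    return NystagmusEvent(
        start_s=span[0],
        end_s=span[1],
        direction=direction,
        direction_weight=weight,
        frequency_class=fclass,
        modal_bin_frequency=f_modal,
        dp_score=dp_score,
    )
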