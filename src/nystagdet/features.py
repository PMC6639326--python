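"""Sliding-window FFT frame features.

A day's signal is cut into 500-sample windows with 80% overlap (hop 100).
Each window is mean-removed and transformed with an FFT; the positive-
frequency amplitude bins whose frequencies fall in the 0.25-7 Hz band are
retained.  At the default 41.5 Hz sampling rate the bins are spaced
fs/500 = 0.083 Hz apart and 82 bins (indices 3..84) survive the band cut.

Band edges are mapped to the nearest bin index (inclusive), which is what
makes the three printed numbers — 500-sample window, 0.25-7 Hz band,
0.083 Hz spacing — consistent with 82 retained bins.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Optional, Sequence

import numpy as np
import scipy.fft

if TYPE_CHECKING:  # pragma: no cover
    from .eog_synth import EogDay


@dataclass(frozen=True)
class FrameSpec:
    """Sliding-window and band parameters for frame feature extraction."""

    window_length: int = 500
    overlap_fraction: float = 0.80
    band_low: float = 0.25
    band_high: float = 7.0
    taper: Optional[str] = None  # None = rectangular; 'hann' supported

    @property
    def hop(self) -> int:
        hop = self.window_length * (1.0 - self.overlap_fraction)
        ihop = int(round(hop))
        if ihop <= 0 or abs(hop - ihop) > 1e-9:
            raise ValueError(
                f"hop = window_length*(1-overlap) must be a positive integer; "
                f"got {hop}"
            )
        return ihop

    def window_duration_s(self, sampling_rate: float) -> float:
        return self.window_length / sampling_rate

    def bin_spacing(self, sampling_rate: float) -> float:
        return sampling_rate / self.window_length

    def retained_bins(self, sampling_rate: float) -> np.ndarray:
        """Indices of the FFT bins kept: nearest bin to each band edge,
        inclusive on both sides."""
        if not self.band_low < self.band_high < sampling_rate / 2:
            raise ValueError(
                "need band_low < band_high < Nyquist; got "
                f"[{self.band_low}, {self.band_high}] at fs={sampling_rate}"
            )
        df = self.bin_spacing(sampling_rate)
        k_lo = int(round(self.band_low / df))
        k_hi = int(round(self.band_high / df))
        return np.arange(max(k_lo, 1), k_hi + 1)


@dataclass
class FrameFeatureMatrix:
    """Per-window amplitude-spectrum features (frames x retained bins)."""

    values: np.ndarray  # (n_frames, n_bins), non-negative
    frame_start_times: np.ndarray  # seconds
    bin_frequencies: np.ndarray  # Hz
    sampling_rate: float
    spec: FrameSpec
    source: object = None  # the EogDay this was derived from, if any

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]

    def to_frame(self):
        """Columnar view (pandas DataFrame) for inspection."""
        import pandas as pd

        cols = {f"f_{f:.3f}Hz": self.values[:, i]
                for i, f in enumerate(self.bin_frequencies)}
        return pd.DataFrame({"frame_time_s": self.frame_start_times, **cols})


def frame_signal(day: "EogDay", spec: FrameSpec = FrameSpec()):
    """Cut a day's signal into overlapping windows at stride ``spec.hop``.

    Returns ``(windows, start_times)`` where ``windows`` is a read-only
    (n_frames, window_length) view and ``start_times`` are window start
    times in seconds.  A trailing partial window is discarded.
    """
    x = np.asarray(day.samples, dtype=float)
    w, hop = spec.window_length, spec.hop
    if len(x) < w:
        raise ValueError(
            f"signal has {len(x)} samples but at least {w} are required "
            f"for one window"
        )
    n_frames = (len(x) - w) // hop + 1
    windows = np.lib.stride_tricks.sliding_window_view(x, w)[::hop][:n_frames]
    starts = np.arange(n_frames) * hop / day.sampling_rate
    return windows, starts


def extract_features(
    windows: np.ndarray,
    spec: FrameSpec,
    sampling_rate: float,
    frame_start_times: Optional[Sequence[float]] = None,
    source: object = None,
) -> FrameFeatureMatrix:
    """Amplitude-spectrum features for a stack of windows.

    Each window is mean-removed (so features are invariant to a constant
    offset), optionally tapered, FFT'd, and the amplitudes 2|X_k|/N of the
    retained positive-frequency bins are kept.
    """
    windows = np.asarray(windows, dtype=float)
    if windows.ndim == 1:
        windows = windows[None, :]
    n = windows.shape[1]
    if n != spec.window_length:
        raise ValueError(
            f"window length {n} does not match spec ({spec.window_length})"
        )
    demeaned = windows - windows.mean(axis=1, keepdims=True)
    if spec.taper == "hann":
        demeaned = demeaned * np.hanning(n)
    elif spec.taper is not None:
        raise ValueError(f"unknown taper {spec.taper!r}")
    spectrum = scipy.fft.rfft(demeaned, axis=1)
    keep = spec.retained_bins(sampling_rate)
    amps = 2.0 * np.abs(spectrum[:, keep]) / n
    freqs = keep * spec.bin_spacing(sampling_rate)
    if frame_start_times is None:
        frame_start_times = np.arange(windows.shape[0]) * spec.hop / sampling_rate
    return FrameFeatureMatrix(
        values=amps,
        frame_start_times=np.asarray(frame_start_times, dtype=float),
        bin_frequencies=freqs,
        sampling_rate=sampling_rate,
        spec=spec,
        source=source,
    )


def day_features(
    day: "EogDay", spec: FrameSpec = FrameSpec(), zscale: bool = False
) -> FrameFeatureMatrix:
    """frame_signal + extract_features for one day.

    ``zscale`` standardises the whole day's signal first — useful when
    comparing wearers, since the EOG amplitude scale is uncalibrated and
    differs between electrode placements.  Off by default (single-wearer
    amplitudes are left untouched).
    """
    if zscale:
        x = np.asarray(day.samples, dtype=float)
        sd = x.std() or 1.0
        day = type(day)(
            samples=(x - x.mean()) / sd,
            sampling_rate=day.sampling_rate,
            calendar_date=day.calendar_date,
            participant_id=day.participant_id,
        )
    windows, starts = frame_signal(day, spec)
    return extract_features(windows, spec, day.sampling_rate, starts, source=day)
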