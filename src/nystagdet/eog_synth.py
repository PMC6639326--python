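"""Synthetic day-scale EOG generation.

Produces seeded horizontal electro-oculography (EOG) day recordings with
embedded sawtooth nystagmus episodes plus the confounders an ambulatory
recording contains: baseline drift, saccadic gaze shifts, broadband sensor
noise, optional periodic artifact bursts (locomotion-like) and optional
impulse artifacts (button-press-like).

Sign convention: positive amplitude = rightward gaze.  A right-beating
nystagmus therefore has a slow phase with negative velocity (slow leftward
drift) and a fast rightward return.

Amplitudes are in arbitrary EOG units; the corneo-retinal potential that
underlies real EOG is uncalibrated in degrees, so only relative amplitudes
are meaningful.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from datetime import date as Date
from datetime import timedelta
from typing import Optional, Sequence

import numpy as np

from .event_typing import NystagmusEvent

DEFAULT_SAMPLING_RATE = 41.5
"""Hz.  Chosen so that a 500-sample analysis window yields 0.083 Hz bins."""

FREQUENCY_CLASSES = (0.8, 1.0, 1.2)
"""Hz.  The three stimulus speeds used for induced nystagmus."""

DIRECTIONS = ("left", "right")

#: minimum sampling rate: the 7 Hz top of the feature band must sit below
#: the Nyquist frequency
MIN_SAMPLING_RATE = 14.0


class ScheduleError(ValueError):
    """Raised when an event schedule is inconsistent (overlap, out of bounds)."""


class ConfigError(ValueError):
    """Raised when a generator configuration violates its invariants."""


@dataclass(frozen=True)
class EventSpec:
    """One scheduled nystagmus episode within a day."""

    onset_s: float
    duration_s: float = 30.0
    frequency_hz: float = 1.0
    direction: str = "right"
    amplitude: float = 1.0

    @property
    def end_s(self) -> float:
        return self.onset_s + self.duration_s


@dataclass(frozen=True)
class ArtifactBurst:
    """A periodic confounder (e.g. locomotion crosstalk): a sinusoidal burst."""

    onset_s: float
    duration_s: float
    frequency_hz: float
    amplitude: float


@dataclass(frozen=True)
class ImpulseArtifact:
    """A short transient (e.g. event-marker button press): a Gaussian pulse."""

    time_s: float
    amplitude: float
    width_s: float


@dataclass(frozen=True)
class GeneratorConfig:
    """Full parameterisation of a synthetic EOG day.

    Parameters
    ----------
    sampling_rate : float
        Hz; must exceed twice the 7 Hz feature-band ceiling.
    day_length : float
        Seconds of signal per day (3600 by default; a full wear-day is
        82800 s = 23 h).
    event_schedule : sequence of EventSpec
        Nystagmus episodes; must not overlap and must lie within the day.
    slow_fast_ratio : float
        Fraction of each beat period occupied by the slow phase (0 < r < 1).
    saccade_rate : float
        Poisson rate (events/s) of step-like gaze shifts.
    saccade_amplitude_range : (float, float)
        Uniform range of saccade step magnitudes (random sign).
    drift_sigma : float
        Random-walk scale of baseline drift, EOG units per sqrt(second).
    noise_sigma : float
        Standard deviation of additive white Gaussian sensor noise.
    artifact_bursts, impulse_artifacts
        Optional confounders (see ArtifactBurst, ImpulseArtifact).
    seed : int
        Base seed; all outputs are pure functions of (config, date, id).
    """

    sampling_rate: float = DEFAULT_SAMPLING_RATE
    day_length: float = 3600.0
    event_schedule: tuple[EventSpec, ...] = ()
    slow_fast_ratio: float = 0.8
    saccade_rate: float = 0.5
    saccade_amplitude_range: tuple[float, float] = (0.3, 1.5)
    drift_sigma: float = 0.05
    noise_sigma: float = 0.15
    artifact_bursts: tuple[ArtifactBurst, ...] = ()
    impulse_artifacts: tuple[ImpulseArtifact, ...] = ()
    frequency_classes: tuple[float, ...] = FREQUENCY_CLASSES
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "event_schedule", tuple(self.event_schedule))
        object.__setattr__(self, "artifact_bursts", tuple(self.artifact_bursts))
        object.__setattr__(
            self, "impulse_artifacts", tuple(self.impulse_artifacts)
        )

    def validate(self) -> None:
        if self.sampling_rate <= MIN_SAMPLING_RATE:
            raise ConfigError(
                f"sampling_rate must exceed {MIN_SAMPLING_RATE} Hz (twice the "
                f"7 Hz feature band); got {self.sampling_rate}"
            )
        if not 0.0 < self.slow_fast_ratio < 1.0:
            raise ConfigError(
                f"slow_fast_ratio must lie in (0, 1); got {self.slow_fast_ratio}"
            )
        if self.day_length <= 0:
            raise ConfigError("day_length must be positive")
        events = sorted(self.event_schedule, key=lambda e: e.onset_s)
        for ev in events:
            if ev.duration_s <= 0:
                raise ScheduleError(f"event duration must be positive: {ev}")
            if ev.onset_s < 0 or ev.end_s > self.day_length:
                raise ScheduleError(
                    f"event [{ev.onset_s}, {ev.end_s}] s outside day "
                    f"[0, {self.day_length}] s"
                )
            if ev.frequency_hz not in self.frequency_classes:
                raise ScheduleError(
                    f"event frequency {ev.frequency_hz} Hz not in configured "
                    f"classes {self.frequency_classes}"
                )
            if ev.direction not in DIRECTIONS:
                raise ScheduleError(f"unknown direction {ev.direction!r}")
        for a, b in zip(events, events[1:]):
            if b.onset_s < a.end_s:
                raise ScheduleError(
                    f"overlapping events at {a.onset_s} s and {b.onset_s} s"
                )


@dataclass
class EogDay:
    """One calendar day of horizontal EOG signal — the unit of detection."""

    samples: np.ndarray
    sampling_rate: float
    calendar_date: Date
    participant_id: str
    event_markers: list[float] = field(default_factory=list)
    ground_truth: Optional[list[NystagmusEvent]] = None
    provenance: str = ""
    metadata: dict = field(default_factory=dict)

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.sampling_rate

    @property
    def n_samples(self) -> int:
        return len(self.samples)


def sawtooth_event(
    frequency: float,
    duration: float,
    direction: str = "right",
    amplitude: float = 1.0,
    slow_fast_ratio: float = 0.8,
    sampling_rate: float = DEFAULT_SAMPLING_RATE,
) -> np.ndarray:
    """Piecewise-linear sawtooth nystagmus waveform.

    Per beat period the waveform spends ``slow_fast_ratio`` of the period in
    a linear slow-phase ramp and the remainder in a fast return ramp.
    Right-beating: slow phase decreasing (negative velocity), fast phase
    increasing, under the positive-equals-rightward gaze convention.
    Left-beating is the sample-wise negation.

    ``amplitude`` is the peak-to-peak excursion; the waveform is centred on
    zero.
    """
    if frequency <= 0:
        raise ValueError(f"frequency must be positive; got {frequency}")
    if duration <= 0:
        raise ValueError(f"duration must be positive; got {duration}")
    if not 0.0 < slow_fast_ratio < 1.0:
        raise ValueError(
            f"slow_fast_ratio must lie in (0, 1); got {slow_fast_ratio}"
        )
    if direction not in DIRECTIONS:
        raise ValueError(f"direction must be one of {DIRECTIONS}")
    n = int(round(duration * sampling_rate))
    t = np.arange(n) / sampling_rate
    phase = (t * frequency) % 1.0
    r = slow_fast_ratio
    slow = phase < r
    out = np.empty(n)
    # slow phase: +A/2 -> -A/2; fast phase: -A/2 -> +A/2
    out[slow] = amplitude * (0.5 - phase[slow] / r)
    out[~slow] = amplitude * (-0.5 + (phase[~slow] - r) / (1.0 - r))
    if direction == "left":
        out = -out
    return out


def _day_rng(config: GeneratorConfig, date: Date, participant_id: str) -> np.random.Generator:
    # derive a stable per-(seed, date, participant) stream
    tag = zlib.crc32(f"{date.isoformat()}|{participant_id}".encode())
    return np.random.default_rng(np.random.SeedSequence([config.seed, tag]))


def synthesize_day(
    config: GeneratorConfig,
    date: Date = Date(2019, 1, 1),
    participant_id: str = "P00",
) -> EogDay:
    """Generate one synthetic EOG day.

    The signal is the sum of a drift random walk, a saccadic step process,
    white Gaussian noise, scheduled artifact bursts and impulses, and the
    scheduled sawtooth nystagmus episodes.  Ground truth is populated from
    the schedule.  Identical (config, date, participant_id) give identical
    output.
    """
    config.validate()
    fs = config.sampling_rate
    n = int(round(config.day_length * fs))
    rng = _day_rng(config, date, participant_id)
    signal = np.zeros(n)

    if config.drift_sigma > 0:
        steps = rng.normal(0.0, config.drift_sigma / np.sqrt(fs), n)
        signal += np.cumsum(steps)

    if config.saccade_rate > 0:
        n_sacc = rng.poisson(config.saccade_rate * config.day_length)
        if n_sacc > 0:
            idx = rng.integers(0, n, n_sacc)
            lo, hi = config.saccade_amplitude_range
            amps = rng.uniform(lo, hi, n_sacc) * rng.choice([-1.0, 1.0], n_sacc)
            jumps = np.zeros(n)
            np.add.at(jumps, idx, amps)
            signal += np.cumsum(jumps)

    if config.noise_sigma > 0:
        signal += rng.normal(0.0, config.noise_sigma, n)

    t = np.arange(n) / fs
    for burst in config.artifact_bursts:
        i0 = int(round(burst.onset_s * fs))
        i1 = min(n, int(round((burst.onset_s + burst.duration_s) * fs)))
        if i1 > i0:
            tt = t[i0:i1] - burst.onset_s
            signal[i0:i1] += burst.amplitude * np.sin(
                2 * np.pi * burst.frequency_hz * tt
            )

    event_markers: list[float] = []
    for imp in config.impulse_artifacts:
        pulse = imp.amplitude * np.exp(
            -0.5 * ((t - imp.time_s) / max(imp.width_s, 1e-6)) ** 2
        )
        signal += pulse
        event_markers.append(imp.time_s)

    ground_truth: list[NystagmusEvent] = []
    for ev in sorted(config.event_schedule, key=lambda e: e.onset_s):
        wave = sawtooth_event(
            ev.frequency_hz,
            ev.duration_s,
            ev.direction,
            ev.amplitude,
            config.slow_fast_ratio,
            fs,
        )
        i0 = int(round(ev.onset_s * fs))
        i1 = min(n, i0 + len(wave))
        signal[i0:i1] += wave[: i1 - i0]
        ground_truth.append(
            NystagmusEvent(
                start_s=ev.onset_s,
                end_s=ev.end_s,
                direction=ev.direction,
                frequency_class=ev.frequency_hz,
            )
        )

    return EogDay(
        samples=signal,
        sampling_rate=fs,
        calendar_date=date,
        participant_id=participant_id,
        event_markers=event_markers,
        ground_truth=ground_truth,
        provenance=f"synthetic (seed={config.seed})",
    )


# ---------------------------------------------------------------------------
# trial-scale replication


@dataclass(frozen=True)
class DayPlan:
    """One planned day-file: at most one nystagmus episode per day."""

    participant_id: str
    date: Date
    stimulus: Optional[tuple[float, str]] = None  # (frequency Hz, direction)


def make_trial_plan(
    n_days: int,
    n_positive: int,
    n_participants: int = 4,
    start_date: Date = Date(2019, 1, 1),
    seed: int = 0,
    classes: Sequence[float] = FREQUENCY_CLASSES,
) -> list[DayPlan]:
    """Build a randomised trial plan: ``n_days`` day-files, ``n_positive`` of
    which carry one nystagmus episode, stimuli cycled uniformly over the
    class x direction combinations."""
    if n_positive > n_days:
        raise ValueError("n_positive cannot exceed n_days")
    rng = np.random.default_rng(seed)
    stimuli = [(f, d) for f in classes for d in DIRECTIONS]
    pos_idx = set(rng.choice(n_days, n_positive, replace=False).tolist())
    # cycle stimuli so all combinations are equally represented, then shuffle
    assigned = [stimuli[i % len(stimuli)] for i in range(n_positive)]
    rng.shuffle(assigned)
    plan: list[DayPlan] = []
    k = 0
    for i in range(n_days):
        pid = f"P{i % n_participants:02d}"
        day_date = start_date + timedelta(days=i // n_participants)
        if i in pos_idx:
            plan.append(DayPlan(pid, day_date, assigned[k]))
            k += 1
        else:
            plan.append(DayPlan(pid, day_date, None))
    return plan


def replicate_trial(
    trial_plan: Sequence[DayPlan],
    config_template: GeneratorConfig,
    master_seed: int = 0,
) -> list[EogDay]:
    """Generate one EogDay per plan cell.

    Positive days carry exactly one 30 s episode at the planned stimulus;
    the onset is drawn uniformly within the day (seeded).  Per-day seeds are
    derived deterministically from ``master_seed``.
    """
    days: list[EogDay] = []
    for i, cell in enumerate(trial_plan):
        day_seed = int(
            np.random.SeedSequence([master_seed, i]).generate_state(1)[0] % (2**31)
        )
        schedule: tuple[EventSpec, ...] = ()
        if cell.stimulus is not None:
            freq, direction = cell.stimulus
            onset_rng = np.random.default_rng(
                np.random.SeedSequence([master_seed, i, 1])
            )
            dur = 30.0
            day_len = config_template.day_length
            if day_len < dur:
                raise ScheduleError(
                    f"day_length {day_len} s cannot hold a {dur} s event"
                )
            margin = min(60.0, 0.25 * (day_len - dur))
            hi = day_len - dur - margin
            if hi <= margin:
                onset = (day_len - dur) / 2.0
            else:
                onset = float(onset_rng.uniform(margin, hi))
            schedule = (EventSpec(onset, dur, freq, direction),)
        cfg = replace(config_template, event_schedule=schedule, seed=day_seed)
        days.append(synthesize_day(cfg, cell.date, cell.participant_id))
    return days
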