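"""End-to-end orchestration: training-set construction, whole-day
detection with event typing, and a desk-scale blinded replication of the
ambulatory trial (generate -> blind -> train -> detect -> type -> unblind
-> evaluate)."""

from __future__ import annotations

from dataclasses import replace
from datetime import date as Date
from typing import Optional, Sequence

import numpy as np

from . import dayio, dxstats
from .detector import (
    DetectorConfig,
    EnsembleHyperparams,
    EnsembleModel,
    detect_day,
    frame_labels,
    train_ensemble,
)
from .eog_synth import (
    DIRECTIONS,
    FREQUENCY_CLASSES,
    EogDay,
    EventSpec,
    GeneratorConfig,
    make_trial_plan,
    replicate_trial,
    synthesize_day,
)
from .event_typing import NystagmusEvent, type_event
from .features import FrameSpec, day_features


def make_training_days(
    n_positive: int = 24,
    n_negative: int = 24,
    day_length: float = 300.0,
    config: Optional[GeneratorConfig] = None,
    seed: int = 1000,
) -> list[EogDay]:
    """Short synthetic days for ensemble training, cycling the positive
    days through all frequency x direction stimulus combinations."""
    if config is None:
        config = GeneratorConfig()
    config = replace(config, day_length=day_length)
    stimuli = [(f, d) for f in config.frequency_classes for d in DIRECTIONS]
    days = []
    rng = np.random.default_rng(seed)
    for i in range(n_positive):
        freq, direction = stimuli[i % len(stimuli)]
        onset = float(rng.uniform(30.0, day_length - 60.0))
        cfg = replace(
            config,
            event_schedule=(EventSpec(onset, 30.0, freq, direction),),
            seed=int(rng.integers(0, 2**31)),
        )
        days.append(synthesize_day(cfg, Date(2018, 1, 1), f"T{i:02d}"))
    for i in range(n_negative):
        cfg = replace(config, event_schedule=(), seed=int(rng.integers(0, 2**31)))
        days.append(synthesize_day(cfg, Date(2018, 2, 1), f"T{n_positive + i:02d}"))
    return days


def train_from_days(
    days: Sequence[EogDay],
    spec: FrameSpec = FrameSpec(),
    hyperparams: EnsembleHyperparams = EnsembleHyperparams(),
    seed: int = 0,
) -> EnsembleModel:
    """Extract frame features and ground-truth frame labels from training
    days and fit the three-member ensemble."""
    feats = [day_features(d, spec) for d in days]
    labels = [frame_labels(d, spec) for d in days]
    return train_ensemble(feats, labels, hyperparams, seed)


def detect_and_type_day(
    model: EnsembleModel,
    day: EogDay,
    spec: FrameSpec = FrameSpec(),
    config: DetectorConfig = DetectorConfig(),
    classes: Sequence[float] = FREQUENCY_CLASSES,
) -> list[NystagmusEvent]:
    """Detect, validate and type the accepted events of one day."""
    runs = detect_day(model, day, spec, config)
    events = []
    for run in runs:
        if not run.accepted:
            continue
        span = (max(0.0, run.start_s), min(day.duration_s, run.end_s))
        events.append(
            type_event(day, span, classes, spec, dp_score=run.dp_score)
        )
    return events


def run_blinded_replication(
    seed: int = 1,
    n_days: int = 120,
    n_positive: int = 40,
    day_length: float = 1800.0,
    config: Optional[GeneratorConfig] = None,
    spec: FrameSpec = FrameSpec(),
    det_config: DetectorConfig = DetectorConfig(),
    n_train_positive: int = 24,
    n_train_negative: int = 24,
) -> dict:
    """Desk-scale blinded replication of the detection trial.

    Generates an evaluation set of ``n_days`` pseudo-days (``n_positive``
    carrying one 30 s episode drawn uniformly from the six stimulus
    combinations), blinds it behind randomised names, trains the ensemble
    on a disjoint synthetic set, runs the full detection and typing chain
    on the blinded days, then unblinds and scores day-level sensitivity/
    specificity and direction/frequency accuracy.

    Returns the evaluation report (see dxstats.evaluate_trial) plus the
    trained model and the blinded dataset.
    """
    if config is None:
        config = GeneratorConfig()
    eval_config = replace(config, day_length=day_length)

    # disjoint training material (different seed stream and day length)
    train_days = make_training_days(
        n_train_positive,
        n_train_negative,
        config=config,
        seed=seed + 500_000,
    )
    model = train_from_days(train_days, spec, seed=seed)

    plan = make_trial_plan(n_days, n_positive, seed=seed + 1)
    days = replicate_trial(plan, eval_config, master_seed=seed + 2)
    flags = [bool(d.ground_truth) for d in days]
    dataset = dayio.randomise_and_blind(days, flags, seed=seed + 3)

    detections = {
        name: detect_and_type_day(model, day, spec, det_config)
        for name, day in dataset.day_files.items()
    }
    report = dxstats.evaluate_trial(detections, dataset.coding_sheet)
    report["model"] = model
    report["dataset"] = dataset
    report["detections"] = detections
    return report
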