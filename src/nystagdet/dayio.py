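"""Trial data management.

Day-files are the unit of the blinded detection task: one calendar day of
signal per file.  This module handles the CSV day-file format (with a JSON
sidecar for ground truth and markers), re-segmentation of continuous
records into calendar days, merging of the half days at the trial
boundaries, and the randomisation/blinding bookkeeping (opaque filenames
plus a coding sheet that only the unblinded evaluator reads).
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from datetime import date as Date
from datetime import datetime, timedelta
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .eog_synth import EogDay
from .event_typing import NystagmusEvent


@dataclass
class ContinuousRecord:
    """A raw device record: uniformly sampled signal from a start time."""

    start: datetime
    samples: np.ndarray
    sampling_rate: float
    participant_id: str

    @property
    def end(self) -> datetime:
        return self.start + timedelta(seconds=len(self.samples) / self.sampling_rate)


@dataclass
class TrialDataset:
    """A blinded collection of day-files plus the coding sheet.

    ``day_files`` maps the randomised opaque name to a blinded EogDay
    (ground truth stripped); ``coding_sheet`` maps the same name back to
    (participant, date, nystagmus-day flag) and retains the withheld ground
    truth for unblinded evaluation.
    """

    day_files: dict[str, EogDay]
    coding_sheet: dict[str, dict]
    blinded: bool = True

    def __post_init__(self):
        if set(self.day_files) != set(self.coding_sheet):
            raise ValueError("coding sheet must be bijective with day-files")


# ---------------------------------------------------------------------------
# day-file format


def write_day_csv(day: EogDay, path, include_ground_truth: bool = True) -> None:
    """Write a day-file: '#'-prefixed header rows, then time_s,amplitude
    rows; ground truth and markers go to a JSON sidecar (same stem)."""
    path = Path(path)
    t = np.arange(day.n_samples) / day.sampling_rate
    with open(path, "w", newline="") as fh:
        fh.write(f"# participant,{day.participant_id}\n")
        fh.write(f"# date,{day.calendar_date.isoformat()}\n")
        fh.write(f"# sampling_rate,{day.sampling_rate}\n")
        fh.write("time_s,amplitude\n")
        pd.DataFrame({"t": t, "a": day.samples}).to_csv(
            fh, header=False, index=False, float_format="%.6f"
        )
    sidecar = {
        "event_markers": list(day.event_markers),
        "provenance": day.provenance,
        "metadata": day.metadata,
    }
    if include_ground_truth and day.ground_truth is not None:
        sidecar["ground_truth"] = [ev.to_dict() for ev in day.ground_truth]
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_day_csv(path) -> EogDay:
    """Read a day-file written by :func:`write_day_csv`."""
    path = Path(path)
    header: dict[str, str] = {}
    with open(path) as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            if not line.startswith("#"):
                fh.seek(pos)
                break
            key, _, value = line[1:].strip().partition(",")
            header[key.strip()] = value.strip()
            pos = fh.tell()
        table = pd.read_csv(fh)
    day = EogDay(
        samples=table["amplitude"].to_numpy(dtype=float),
        sampling_rate=float(header["sampling_rate"]),
        calendar_date=Date.fromisoformat(header["date"]),
        participant_id=header["participant"],
    )
    sidecar_path = path.with_suffix(".json")
    if sidecar_path.exists():
        sidecar = json.loads(sidecar_path.read_text())
        day.event_markers = list(sidecar.get("event_markers", []))
        day.provenance = sidecar.get("provenance", "")
        day.metadata = sidecar.get("metadata", {})
        if "ground_truth" in sidecar:
            day.ground_truth = [
                NystagmusEvent.from_dict(d) for d in sidecar["ground_truth"]
            ]
    return day


def write_detections(detections: dict[str, list[NystagmusEvent]], path) -> None:
    """Detections file: JSON mapping day identifier -> list of events."""
    payload = {
        name: [ev.to_dict() for ev in events] for name, events in detections.items()
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_detections(path) -> dict[str, list[NystagmusEvent]]:
    payload = json.loads(Path(path).read_text())
    return {
        name: [NystagmusEvent.from_dict(d) for d in events]
        for name, events in payload.items()
    }


def write_record_csv(record: ContinuousRecord, path) -> None:
    """Continuous-record file: like a day-file but headed by a full start
    timestamp instead of a calendar date."""
    path = Path(path)
    t = np.arange(len(record.samples)) / record.sampling_rate
    with open(path, "w", newline="") as fh:
        fh.write(f"# participant,{record.participant_id}\n")
        fh.write(f"# start,{record.start.isoformat()}\n")
        fh.write(f"# sampling_rate,{record.sampling_rate}\n")
        fh.write("time_s,amplitude\n")
        pd.DataFrame({"t": t, "a": record.samples}).to_csv(
            fh, header=False, index=False, float_format="%.6f"
        )


def read_record_csv(path) -> ContinuousRecord:
    path = Path(path)
    header: dict[str, str] = {}
    with open(path) as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            if not line.startswith("#"):
                fh.seek(pos)
                break
            key, _, value = line[1:].strip().partition(",")
            header[key.strip()] = value.strip()
            pos = fh.tell()
        table = pd.read_csv(fh)
    return ContinuousRecord(
        start=datetime.fromisoformat(header["start"]),
        samples=table["amplitude"].to_numpy(dtype=float),
        sampling_rate=float(header["sampling_rate"]),
        participant_id=header["participant"],
    )


# ---------------------------------------------------------------------------
# calendar-day re-segmentation


def resegment(
    records: Sequence[ContinuousRecord], clock_policy: str = "face-value"
) -> list[EogDay]:
    """Partition continuous records into calendar-day files.

    Multiple records falling on the same date (e.g. either side of a battery
    change) are concatenated, with the gap logged in the day's metadata.
    Device timestamps are taken at face value (no drift or daylight-saving
    correction).
    """
    if clock_policy != "face-value":
        raise ValueError("only the 'face-value' clock policy is implemented")
    records = sorted(records, key=lambda r: (r.participant_id, r.start))
    for a, b in zip(records, records[1:]):
        if a.participant_id == b.participant_id and b.start < a.end:
            raise ValueError(
                f"records overlap for {a.participant_id} at {b.start}"
            )
    pieces: dict[tuple[str, Date], list[tuple[datetime, np.ndarray, float]]] = {}
    for rec in records:
        fs = rec.sampling_rate
        start = rec.start
        remaining = np.asarray(rec.samples, dtype=float)
        while len(remaining):
            day_end = datetime.combine(
                start.date() + timedelta(days=1), datetime.min.time()
            )
            n_take = min(
                len(remaining), int(round((day_end - start).total_seconds() * fs))
            )
            if n_take <= 0:
                break
            pieces.setdefault((rec.participant_id, start.date()), []).append(
                (start, remaining[:n_take], fs)
            )
            remaining = remaining[n_take:]
            start = day_end
    days = []
    for (pid, date), chunks in sorted(pieces.items()):
        chunks.sort(key=lambda c: c[0])
        gaps = []
        for (s0, x0, fs0), (s1, _x1, _fs1) in zip(chunks, chunks[1:]):
            gap_s = (s1 - s0).total_seconds() - len(x0) / fs0
            if gap_s > 0.5 / fs0:
                gaps.append(
                    {"at": s1.isoformat(), "gap_s": round(float(gap_s), 3)}
                )
        days.append(
            EogDay(
                samples=np.concatenate([c[1] for c in chunks]),
                sampling_rate=chunks[0][2],
                calendar_date=date,
                participant_id=pid,
                metadata={"gaps": gaps} if gaps else {},
                provenance=f"resegmented from {len(chunks)} record(s)",
            )
        )
    return days


def merge_partial_days(first_day: EogDay, last_day: EogDay) -> EogDay:
    """Combine the trial's first and last half days into one pseudo-day.

    The result carries the first day's date; the seam time (seconds from
    the start of the merged signal) is recorded in metadata.
    """
    if first_day.participant_id != last_day.participant_id:
        raise ValueError("cannot merge days from different participants")
    if not first_day.calendar_date < last_day.calendar_date:
        raise ValueError("first_day must precede last_day")
    if first_day.sampling_rate != last_day.sampling_rate:
        raise ValueError("sampling rates differ")
    seam_s = first_day.duration_s
    gt = None
    if first_day.ground_truth is not None or last_day.ground_truth is not None:
        gt = list(first_day.ground_truth or [])
        for ev in last_day.ground_truth or []:
            d = ev.to_dict()
            d["start_s"] += seam_s
            d["end_s"] += seam_s
            gt.append(NystagmusEvent.from_dict(d))
    return EogDay(
        samples=np.concatenate([first_day.samples, last_day.samples]),
        sampling_rate=first_day.sampling_rate,
        calendar_date=first_day.calendar_date,
        participant_id=first_day.participant_id,
        event_markers=list(first_day.event_markers)
        + [t + seam_s for t in last_day.event_markers],
        ground_truth=gt,
        provenance=(
            f"merged half days {first_day.calendar_date} + {last_day.calendar_date}"
        ),
        metadata={"seam_s": seam_s},
    )


# ---------------------------------------------------------------------------
# blinding


def randomise_and_blind(
    days: Sequence[EogDay],
    ground_truth_flags: Sequence[bool],
    seed: int = 0,
) -> TrialDataset:
    """Assign shuffled opaque filenames and emit the coding sheet.

    Detection consumers receive signal-only copies (ground truth and event
    markers withheld); the coding sheet retains everything needed for
    unblinded evaluation.
    """
    if len(days) != len(ground_truth_flags):
        raise ValueError("one ground-truth flag per day is required")
    identities = [(d.participant_id, d.calendar_date) for d in days]
    if len(set(identities)) != len(identities):
        raise ValueError("duplicate (participant, date) day identities")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(days))
    width = max(4, len(str(len(days))))
    day_files: dict[str, EogDay] = {}
    sheet: dict[str, dict] = {}
    for rank, idx in enumerate(order):
        day = days[idx]
        name = f"day_{rank:0{width}d}"
        blinded = EogDay(
            samples=day.samples,
            sampling_rate=day.sampling_rate,
            calendar_date=day.calendar_date,
            participant_id=name,  # identity withheld
            provenance="blinded",
        )
        day_files[name] = blinded
        sheet[name] = {
            "participant": day.participant_id,
            "date": day.calendar_date.isoformat(),
            "nystagmus_day": bool(ground_truth_flags[idx]),
            "ground_truth": [ev.to_dict() for ev in day.ground_truth or []],
        }
    return TrialDataset(day_files=day_files, coding_sheet=sheet, blinded=True)


def unblind(dataset: TrialDataset) -> list[EogDay]:
    """Recover the original day identities from the coding sheet."""
    days = []
    for name, day in dataset.day_files.items():
        entry = dataset.coding_sheet[name]
        days.append(
            EogDay(
                samples=day.samples,
                sampling_rate=day.sampling_rate,
                calendar_date=Date.fromisoformat(entry["date"]),
                participant_id=entry["participant"],
                ground_truth=[
                    NystagmusEvent.from_dict(d) for d in entry["ground_truth"]
                ],
            )
        )
    return days


def write_coding_sheet(dataset: TrialDataset, path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["file", "participant", "date", "nystagmus_day", "ground_truth_json"]
        )
        for name in sorted(dataset.coding_sheet):
            e = dataset.coding_sheet[name]
            writer.writerow(
                [
                    name,
                    e["participant"],
                    e["date"],
                    int(e["nystagmus_day"]),
                    json.dumps(e["ground_truth"]),
                ]
            )


def read_coding_sheet(path) -> dict[str, dict]:
    sheet: dict[str, dict] = {}
    with open(path) as fh:
        for row in csv.DictReader(fh):
            sheet[row["file"]] = {
                "participant": row["participant"],
                "date": row["date"],
                "nystagmus_day": bool(int(row["nystagmus_day"])),
                "ground_truth": json.loads(row["ground_truth_json"]),
            }
    return sheet


def label_from_markers(
    days: Sequence[EogDay], tolerance_s: float = 60.0
) -> list[bool]:
    """Flag days whose event-marker presses coincide with a ground-truth
    event (mimicking the manual verification step of a wearable trial)."""
    flags = []
    for day in days:
        hit = False
        for t in day.event_markers:
            for ev in day.ground_truth or []:
                if ev.start_s - tolerance_s <= t <= ev.end_s + tolerance_s:
                    hit = True
        flags.append(hit)
    return flags
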