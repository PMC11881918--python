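"""File formats: TIFF stacks, CSV traces and event tables, JSON/YAML metadata.

All CSV files use UTF-8, '.' decimal separator and a header row so they
round-trip bit-exactly.  Image stacks are multi-page grayscale TIFF with
a small JSON sidecar (``<name>.json``) holding the frame rate.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import List, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

from .core import ImageStack, Roi, Trace
from .events import ContractionEvent, DetectionReport
from .synthetic import EventSchedule, ScheduledEvent, SimConfig

__all__ = [
    "write_stack", "read_stack",
    "write_trace", "read_trace",
    "write_schedule", "read_schedule",
    "write_config", "read_config",
    "write_roi", "read_roi",
    "events_to_frame", "write_events", "read_events",
    "write_report", "sha256_of",
]


def write_stack(path, stack: ImageStack) -> Path:
    path = Path(path)
    tifffile.imwrite(path, stack.frames.astype(np.float32))
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps({"frame_rate": stack.frame_rate,
                                   "t0": stack.t0}))
    return path


def read_stack(path, frame_rate: float = 2.0) -> ImageStack:
    path = Path(path)
    frames = tifffile.imread(path)
    t0 = 0.0
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        frame_rate = meta.get("frame_rate", frame_rate)
        t0 = meta.get("t0", 0.0)
    return ImageStack(frames=np.asarray(frames, dtype=float),
                      frame_rate=frame_rate, t0=t0)


def write_trace(path, trace: Trace) -> Path:
    path = Path(path)
    pd.DataFrame({"time_s": trace.times, "value": trace.values}).to_csv(
        path, index=False)
    return path


def read_trace(path, name: str = "") -> Trace:
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy(dtype=float)
    if len(t) < 2:
        raise ValueError("trace file needs at least two samples")
    dt = float(np.median(np.diff(t)))
    return Trace(values=df["value"].to_numpy(dtype=float), dt=dt,
                 t0=float(t[0]), name=name or Path(path).stem)


def write_schedule(path, schedule: EventSchedule) -> Path:
    path = Path(path)
    payload = {
        "total_duration": schedule.total_duration,
        "seed": schedule.seed,
        "events": [dataclasses.asdict(ev) for ev in schedule.events],
    }
    path.write_text(json.dumps(payload, indent=2))
    return path


def read_schedule(path) -> EventSchedule:
    payload = json.loads(Path(path).read_text())
    events = [ScheduledEvent(**ev) for ev in payload["events"]]
    return EventSchedule(events=events,
                         total_duration=payload["total_duration"],
                         seed=payload.get("seed", 0))


def write_config(path, config: SimConfig) -> Path:
    path = Path(path)
    d = dataclasses.asdict(config)
    d["image_size"] = list(d["image_size"])
    d["duration_range"] = list(d["duration_range"])
    d["amplitude_range"] = list(d["amplitude_range"])
    path.write_text(yaml.safe_dump(d, sort_keys=True))
    return path


def read_config(path) -> SimConfig:
    d = yaml.safe_load(Path(path).read_text())
    for key in ("image_size", "duration_range", "amplitude_range"):
        if key in d:
            d[key] = tuple(d[key])
    return SimConfig(**d)


def write_roi(path, roi: Roi) -> Path:
    path = Path(path)
    payload = {"label": roi.label}
    if roi.rect is not None:
        payload["rect"] = list(roi.rect)
    else:
        payload["mask"] = roi.mask.astype(int).tolist()
    path.write_text(json.dumps(payload))
    return path


def read_roi(path) -> Roi:
    payload = json.loads(Path(path).read_text())
    if "rect" in payload:
        return Roi(label=payload.get("label", "roi"),
                   rect=tuple(payload["rect"]))
    return Roi(label=payload.get("label", "roi"),
               mask=np.asarray(payload["mask"], dtype=bool))


def events_to_frame(events: Sequence[ContractionEvent]) -> pd.DataFrame:
    rows = []
    for i, e in enumerate(events):
        rows.append({
            "event_id": i,
            "start_s": e.start,
            "end_s": e.end,
            "duration_s": e.duration,
            "signature": "".join(f"{v:+d}"[0] for v in e.signature),
            "strength_au": e.strength,
            "max_velocity_au_per_s": e.max_velocity,
        })
    return pd.DataFrame(rows, columns=[
        "event_id", "start_s", "end_s", "duration_s", "signature",
        "strength_au", "max_velocity_au_per_s"])


def write_events(path, events: Sequence[ContractionEvent]) -> Path:
    path = Path(path)
    events_to_frame(events).to_csv(path, index=False)
    return path


def read_events(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_report(path, report: DetectionReport) -> Path:
    path = Path(path)
    payload = {
        "sensitivity": report.sensitivity,
        "ppv": report.ppv,
        "n_true": report.n_true,
        "n_predicted": report.n_predicted,
        "n_matched": report.n_matched,
        "false_positives": report.false_positives,
        "false_negatives": report.false_negatives,
        "tolerance_s": report.tolerance,
        "ppv_undefined": report.ppv_undefined,
    }
    path.write_text(json.dumps(payload, indent=2))
    return path


def sha256_of(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
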