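"""End-to-end runs: simulate -> flow -> kinematics -> detect -> report.

``run_pipeline`` executes the whole chain on a simulated recording and
writes every intermediate product plus a manifest (config, seeds, output
checksums) into a run directory, so a run is reproducible and auditable.
``benchmark_detector`` scores the trace-level detector against ground
truth over many simulated recordings.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np

from . import io as mio
from .core import Roi
from .events import (DetectionReport, detect_events, evaluate_detection)
from .flow import (cumulative_displacement, estimate_stack_fields,
                   flow_change, flow_strength, smooth_trace)
from .kinematics import fit_direction, projected_velocity
from .core import Trace
from .synthetic import (EventSchedule, SimConfig, generate_contraction_movie,
                        generate_displacement_trace, generate_event_schedule)

__all__ = ["RunConfig", "run_pipeline", "benchmark_detector"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All stage parameters for one reproducible pipeline run."""

    sim: SimConfig = field(default_factory=SimConfig)
    block_size: int = 16
    search_radius: int = 10
    smooth_window: int = 5            # samples (2.5 s at 2 Hz)
    thresholds: Tuple[float, float, float] = (0.35, 0.25, 0.15)
    min_duration: float = 15.0        # s, strict
    max_duration: float = 30.0        # s, strict
    match_tolerance: float = 5.0      # s, midpoint matching
    detection_trace: str = "projected"  # or "flow_strength"
    movie_direction: Optional[float] = 0.0  # common motion axis, radians

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sim"]["image_size"] = list(d["sim"]["image_size"])
        d["sim"]["duration_range"] = list(d["sim"]["duration_range"])
        d["sim"]["amplitude_range"] = list(d["sim"]["amplitude_range"])
        d["thresholds"] = list(d["thresholds"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        sim = d.pop("sim", {})
        for key in ("image_size", "duration_range", "amplitude_range"):
            if key in sim:
                sim[key] = tuple(sim[key])
        d["thresholds"] = tuple(d.get("thresholds", (0.35, 0.25, 0.15)))
        return cls(sim=SimConfig(**sim), **d)


def run_pipeline(config: RunConfig, out_dir) -> Path:
    """Simulate a movie, extract traces, detect events, score and manifest.

    Stage order: simulation (movie + ground truth), displacement fields
    against frame 0, flow-strength and smoothed traces, cumulative x/y and
    projected-velocity trace, event detection, scoring against the true
    schedule, and output writing.  Identical configs (same seeds) produce
    byte-identical event tables.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    try:
        stack, truth = generate_contraction_movie(
            config.sim, direction=config.movie_direction)
        mio.write_stack(out / "stack.tif", stack)
        mio.write_schedule(out / "schedule.json", truth.schedule)
    except Exception as exc:  # pragma: no cover - defensive
        raise RuntimeError(f"[simulate] {exc}") from exc

    try:
        roi = Roi.full_frame(stack.shape)
        fields = estimate_stack_fields(stack, config.block_size,
                                       config.search_radius)
        s_raw = Trace(
            values=[flow_strength(f, roi, stack.shape) for f in fields],
            dt=stack.dt, name="flow_strength")
        s_smooth = smooth_trace(s_raw, config.smooth_window)
        c = flow_change(s_smooth)
        x, y = cumulative_displacement(fields, roi, stack.shape, stack.dt)
        x_s = smooth_trace(x, config.smooth_window)
        y_s = smooth_trace(y, config.smooth_window)
        mio.write_trace(out / "flow_strength.csv", s_smooth)
        mio.write_trace(out / "flow_change.csv", c)
    except Exception as exc:
        raise RuntimeError(f"[flow] {exc}") from exc

    try:
        if config.detection_trace == "projected":
            # direction fitted on smoothed coordinates; the detection trace
            # itself stays unsmoothed so event metrics see raw samples
            # (detect_events smooths its own working copy)
            direction = fit_direction(x_s, y_s)
            det_trace = projected_velocity(x, y, direction)
            (out / "direction.json").write_text(json.dumps(
                {"X": direction.X, "Y": direction.Y,
                 "a": direction.a, "L": direction.L}))
        else:
            det_trace = s_smooth
        mio.write_trace(out / "detection_trace.csv", det_trace)
    except Exception as exc:
        raise RuntimeError(f"[kinematics] {exc}") from exc

    try:
        events = detect_events(det_trace, thresholds=config.thresholds,
                               min_dur=config.min_duration,
                               max_dur=config.max_duration,
                               smooth_window=config.smooth_window)
        mio.write_events(out / "events.csv", events)
    except Exception as exc:
        raise RuntimeError(f"[detect] {exc}") from exc

    try:
        report = evaluate_detection(events, truth.schedule,
                                    tolerance=config.match_tolerance)
        mio.write_report(out / "report.json", report)
    except Exception as exc:
        raise RuntimeError(f"[metrics] {exc}") from exc

    outputs = sorted(p for p in out.iterdir()
                     if p.is_file() and p.name != "manifest.json")
    manifest = {
        "config": config.to_dict(),
        "outputs": {p.name: mio.sha256_of(p) for p in outputs},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out


def benchmark_detector(
    n_traces: int = 30,
    seeds: Optional[Sequence[int]] = None,
    config: Optional[SimConfig] = None,
    events_per_trace: Tuple[int, int] = (4, 8),
    thresholds: Tuple[float, float, float] = (0.35, 0.25, 0.15),
    min_dur: float = 15.0,
    max_dur: float = 30.0,
    tolerance: float = 5.0,
) -> DetectionReport:
    """Pooled detector performance over many simulated recordings.

    Each recording draws its own event count uniformly from
    ``events_per_trace`` (inclusive) and its own schedule, trace noise and
    seed; predictions are matched to ground truth per recording and the
    TP/FP/FN counts are pooled before computing sensitivity and PPV.
    """
    if config is None:
        config = SimConfig()
    if seeds is None:
        seeds = range(1, n_traces + 1)
    tp = fp = fn = n_true = n_pred = 0
    for seed in seeds:
        cfg = dataclasses.replace(config, seed=int(seed))
        rng = np.random.default_rng(cfg.seed)
        n_events = int(rng.integers(events_per_trace[0],
                                    events_per_trace[1] + 1))
        schedule = generate_event_schedule(cfg, n_events=n_events, rng=rng)
        trace, truth = generate_displacement_trace(schedule, cfg, rng=rng)
        events = detect_events(trace, thresholds=thresholds,
                               min_dur=min_dur, max_dur=max_dur)
        rep = evaluate_detection(events, truth.schedule, tolerance=tolerance)
        tp += rep.n_matched
        fp += rep.false_positives
        fn += rep.false_negatives
        n_true += rep.n_true
        n_pred += rep.n_predicted
    sensitivity = tp / (tp + fn) if (tp + fn) else 1.0
    ppv = tp / (tp + fp) if (tp + fp) else 0.0
    return DetectionReport(sensitivity=sensitivity, ppv=ppv, n_true=n_true,
                           n_predicted=n_pred, n_matched=tp,
                           tolerance=tolerance,
                           ppv_undefined=(tp + fp) == 0 and n_true > 0)
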