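"""Synthetic ground-truth generators for every pipeline stage.

Generates (a) event schedules and 1-D displacement traces with episodic
biphasic contraction-relaxation pulses on a quiescent baseline, (b)
textured image stacks warped by a known displacement field, (c) Hill-shaped
dose-response tables, and (d) voltage-ramp current recordings with inward
rectification.  Everything is seeded and reproducible, and the clean
(noiseless) truth is always returned alongside the noisy observable, so
downstream stages can be benchmarked without any external data.

The biphasic pulse is two opposed raised-cosine lobes: the first lobe
occupies 60% of the event duration with amplitude ``a`` and the second,
opposite-signed lobe occupies the remaining 40%, scaled so the two lobe
areas cancel (the pulse integrates to zero).  A contraction-first event
has a positive first lobe; relaxation-first is the mirror image.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .core import ImageStack, Trace

__all__ = [
    "SimConfig",
    "ScheduledEvent",
    "EventSchedule",
    "GroundTruth",
    "DoseResponsePoint",
    "generate_event_schedule",
    "generate_displacement_trace",
    "generate_contraction_movie",
    "generate_dose_response",
    "generate_ramp_recording",
]

logger = logging.getLogger(__name__)

POSITIVE_LOBE_FRACTION = 0.6


@dataclass
class SimConfig:
    """Study conditions for the synthetic recordings.

    Defaults mirror the acquisition and detection setup the pipeline is
    built for: 600-s recordings at 2 Hz, 6 events per 10 min with
    durations drawn strictly inside the (15, 30)-s retention band so the
    duration filter is lossless on truth, inter-event gaps of at least
    5 s, and additive Gaussian noise (trace noise 5% of the maximum pulse
    amplitude; movie pixel noise 2% of the texture dynamic range).
    """

    frame_rate: float = 2.0              # Hz
    total_duration: float = 600.0        # s
    image_size: Tuple[int, int] = (64, 64)
    texture_granularity: float = 3.0     # Gaussian smoothing sigma, px
    event_rate_per_10min: float = 6.0
    duration_range: Tuple[float, float] = (16.0, 29.0)   # s
    amplitude_range: Tuple[float, float] = (0.5, 1.5)    # a.u. (px for movies)
    min_gap: float = 5.0                 # s of quiescence between events
    trace_noise_frac: float = 0.05       # sd as fraction of max amplitude
    movie_noise_frac: float = 0.02       # sd as fraction of dynamic range
    flow_search_radius: int = 10         # px; used only to warn on large warps
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if min(self.image_size) < 32:
            raise ValueError("image size must be at least 32 x 32")
        if self.total_duration <= 0:
            raise ValueError("total_duration must be positive")
        lo, hi = self.amplitude_range
        if lo <= 0 or hi < lo:
            raise ValueError("amplitude_range must be positive and ordered")

    @property
    def dt(self) -> float:
        return 1.0 / self.frame_rate

    @property
    def trace_noise_sd(self) -> float:
        return self.trace_noise_frac * self.amplitude_range[1]


@dataclass(frozen=True)
class ScheduledEvent:
    """One true contraction-relaxation episode."""

    onset: float        # s
    duration: float     # s
    amplitude: float    # positive-lobe amplitude, a.u.
    contraction_first: bool = True
    direction: float = 0.0  # motion axis angle for movies, radians

    @property
    def offset(self) -> float:
        return self.onset + self.duration

    @property
    def midpoint(self) -> float:
        return self.onset + 0.5 * self.duration


@dataclass
class EventSchedule:
    """Ground-truth event list for one recording."""

    events: List[ScheduledEvent]
    total_duration: float
    seed: int = 0

    def __post_init__(self) -> None:
        self.events = sorted(self.events, key=lambda e: e.onset)
        for ev in self.events:
            if ev.amplitude <= 0:
                raise ValueError("event amplitude must be positive")
            if ev.onset < 0 or ev.offset > self.total_duration:
                raise ValueError("event exceeds the recording span")
        for a, b in zip(self.events, self.events[1:]):
            if b.onset < a.offset:
                raise ValueError("events overlap")

    def __len__(self) -> int:
        return len(self.events)


@dataclass
class GroundTruth:
    """What the generator actually simulated, for benchmarking."""

    schedule: EventSchedule
    trace_clean: Trace
    parameters: dict = field(default_factory=dict)


@dataclass(frozen=True)
class DoseResponsePoint:
    """One concentration / fold-increase observation."""

    concentration: float   # uM
    fold_increase: float   # dimensionless

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise ValueError("concentration must be non-negative")


def generate_event_schedule(
    config: SimConfig,
    n_events: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> EventSchedule:
    """Place non-overlapping biphasic events with >= min_gap quiescence.

    Durations are sampled uniformly inside ``config.duration_range`` (by
    default strictly within the (15, 30)-s retention band), amplitudes
    uniformly in ``config.amplitude_range``, polarity fair-coin.  Gaps of
    at least ``min_gap`` separate events from each other and from both
    recording edges; the remaining slack is spread randomly.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    if n_events is None:
        n_events = int(round(config.event_rate_per_10min
                             * config.total_duration / 600.0))
    if n_events < 0:
        raise ValueError("event count must be non-negative")
    if n_events == 0:
        return EventSchedule(events=[], total_duration=config.total_duration,
                             seed=config.seed)

    durations = rng.uniform(*config.duration_range, size=n_events)
    amplitudes = rng.uniform(*config.amplitude_range, size=n_events)
    contraction_first = rng.random(n_events) < 0.5
    directions = rng.uniform(0.0, 2 * np.pi, size=n_events)

    occupied = durations.sum() + (n_events + 1) * config.min_gap
    slack = config.total_duration - occupied
    if slack < 0:
        raise ValueError(
            f"cannot place {n_events} events of mean duration "
            f"{durations.mean():.1f} s with {config.min_gap} s gaps in "
            f"{config.total_duration} s")
    # distribute the slack over the n_events + 1 gaps
    extra = rng.dirichlet(np.ones(n_events + 1)) * slack
    events = []
    t = 0.0
    for i in range(n_events):
        t += config.min_gap + extra[i]
        events.append(ScheduledEvent(
            onset=t, duration=float(durations[i]),
            amplitude=float(amplitudes[i]),
            contraction_first=bool(contraction_first[i]),
            direction=float(directions[i]),
        ))
        t += durations[i]
    return EventSchedule(events=events, total_duration=config.total_duration,
                         seed=config.seed)


def biphasic_pulse(t: np.ndarray, event: ScheduledEvent) -> np.ndarray:
    """Zero-integral biphasic pulse evaluated on the time grid ``t``.

    First lobe: raised cosine of amplitude ``a`` over the first 60% of
    the event.  Second lobe: opposite sign over the remaining 40%, with
    amplitude a * 0.6/0.4 so the areas cancel exactly.
    """
    t1 = POSITIVE_LOBE_FRACTION * event.duration
    t2 = event.duration - t1
    u = t - event.onset
    out = np.zeros_like(t, dtype=float)
    first = (u >= 0) & (u < t1)
    second = (u >= t1) & (u <= event.duration)
    out[first] = 0.5 * event.amplitude * (1 - np.cos(2 * np.pi * u[first] / t1))
    amp2 = event.amplitude * t1 / t2
    out[second] = -0.5 * amp2 * (1 - np.cos(2 * np.pi * (u[second] - t1) / t2))
    if not event.contraction_first:
        out = -out
    return out


def clean_trace_from_schedule(schedule: EventSchedule, config: SimConfig) -> Trace:
    """Noiseless superposition of all scheduled pulses on the frame grid."""
    n = int(round(config.total_duration * config.frame_rate)) + 1
    t = np.arange(n) * config.dt
    v = np.zeros(n)
    for ev in schedule.events:
        v += biphasic_pulse(t, ev)
    return Trace(values=v, dt=config.dt, name="displacement_clean")


def generate_displacement_trace(
    schedule: EventSchedule,
    config: SimConfig,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[Trace, GroundTruth]:
    """Noisy 1-D displacement trace plus its noiseless ground truth.

    Additive zero-mean Gaussian noise with sd = trace_noise_frac times the
    maximum positive-lobe amplitude of the configuration.
    """
    if schedule.total_duration > config.total_duration + 1e-9:
        raise ValueError("schedule exceeds the configured duration")
    rng = np.random.default_rng(config.seed) if rng is None else rng
    clean = clean_trace_from_schedule(schedule, config)
    sd = config.trace_noise_sd
    noisy = clean.values + (rng.normal(0.0, sd, len(clean)) if sd > 0 else 0.0)
    trace = clean.with_values(noisy, name="displacement")
    truth = GroundTruth(schedule=schedule, trace_clean=clean,
                        parameters={"noise_sd": sd,
                                    "frame_rate": config.frame_rate})
    return trace, truth


def _band_limited_texture(shape: Tuple[int, int], sigma: float,
                          rng: np.random.Generator) -> np.ndarray:
    """Smoothed white noise rescaled to [0, 1]; unambiguous for matching."""
    raw = ndimage.gaussian_filter(rng.standard_normal(shape), sigma)
    lo, hi = raw.min(), raw.max()
    return (raw - lo) / (hi - lo)


def generate_contraction_movie(
    config: SimConfig,
    schedule: Optional[EventSchedule] = None,
    direction: Optional[float] = None,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[ImageStack, GroundTruth]:
    """Image stack of a textured field rigidly warped by the pulse train.

    Frame 0 is the relaxed reference texture.  During an event the whole
    field translates along the event's motion axis with the biphasic pulse
    as signed magnitude (spatially uniform), so the ground-truth mean
    displacement is exactly the 1-D clean trace.  Per-pixel Gaussian noise
    is added to every frame.  Passing ``direction`` forces one common
    motion axis for all events (useful for projection tests).
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    if schedule is None:
        schedule = generate_event_schedule(config, rng=rng)
    if direction is not None:
        schedule = replace(schedule, events=[
            replace(ev, direction=float(direction)) for ev in schedule.events])

    clean = clean_trace_from_schedule(schedule, config)
    peak_disp = np.abs(clean.values).max(initial=0.0)
    if peak_disp > config.flow_search_radius:
        logger.warning(
            "peak displacement %.1f px exceeds the flow search radius %d px; "
            "the flow stage will underestimate it", peak_disp,
            config.flow_search_radius)

    texture = _band_limited_texture(config.image_size, config.texture_granularity, rng)
    n_frames = len(clean)
    t = clean.times
    dx = np.zeros(n_frames)
    dy = np.zeros(n_frames)
    for ev in schedule.events:
        pulse = biphasic_pulse(t, ev)
        dx += pulse * np.cos(ev.direction)
        dy += pulse * np.sin(ev.direction)

    noise_sd = config.movie_noise_frac  # texture dynamic range is 1.0
    frames = np.empty((n_frames, *config.image_size))
    for i in range(n_frames):
        if dx[i] == 0.0 and dy[i] == 0.0:
            warped = texture
        else:
            # content moves by (dx, dy): sample the texture at r - d
            warped = ndimage.shift(texture, shift=(dy[i], dx[i]),
                                   order=3, mode="reflect")
        frames[i] = warped
        if noise_sd > 0:
            frames[i] = frames[i] + rng.normal(0.0, noise_sd, config.image_size)

    stack = ImageStack(frames=frames, frame_rate=config.frame_rate)
    truth = GroundTruth(schedule=schedule, trace_clean=clean,
                        parameters={"dx": dx, "dy": dy,
                                    "noise_sd": noise_sd,
                                    "frame_rate": config.frame_rate})
    return stack, truth


def hill_activation(c, ec50: float, hill: float, plateau: float) -> np.ndarray:
    """FI(c) = 1 + (plateau - 1) c^h / (c^h + EC50^h); FI(0) = 1."""
    c = np.asarray(c, dtype=float)
    ch = np.power(c, hill, where=c > 0, out=np.zeros_like(c))
    return 1.0 + (plateau - 1.0) * ch / (ch + ec50 ** hill)


def hill_inhibition(c, ic50: float, hill: float, top: float) -> np.ndarray:
    """FI(c) = top - (top - 1) c^h / (c^h + IC50^h); decays from top to 1."""
    c = np.asarray(c, dtype=float)
    ch = np.power(c, hill, where=c > 0, out=np.zeros_like(c))
    return top - (top - 1.0) * ch / (ch + ic50 ** hill)


def generate_dose_response(
    ec50: float,
    hill: float,
    plateau_fi: float,
    concentrations: Sequence[float],
    noise_sd: float = 0.0,
    seed: Optional[int] = None,
    mode: str = "activation",
) -> List[DoseResponsePoint]:
    """Noisy Hill-shaped fold-increase observations with known parameters."""
    if ec50 <= 0 or hill <= 0:
        raise ValueError("ec50 and hill must be positive")
    if plateau_fi <= 1:
        raise ValueError("plateau fold-increase must exceed 1")
    conc = np.asarray(concentrations, dtype=float)
    if (conc < 0).any():
        raise ValueError("concentrations must be non-negative")
    if mode == "activation":
        fi = hill_activation(conc, ec50, hill, plateau_fi)
    elif mode == "inhibition":
        fi = hill_inhibition(conc, ec50, hill, plateau_fi)
    else:
        raise ValueError("mode must be 'activation' or 'inhibition'")
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        fi = fi + rng.normal(0.0, noise_sd, len(conc))
    return [DoseResponsePoint(concentration=float(c), fold_increase=float(f))
            for c, f in zip(conc, fi)]


def generate_ramp_recording(
    conductance: float,
    reversal: float = 0.0,
    rect_vhalf: float = -20.0,
    rect_slope: float = 30.0,
    capacitance: float = 14.0,
    noise: float = 0.0,
    seed: Optional[int] = None,
    n_points: int = 321,
    v_range: Tuple[float, float] = (-80.0, 80.0),
    label: str = "synthetic",
):
    """Voltage-ramp current of an inwardly rectifying conductance.

    I(V) = g (V - E_rev) r(V) with the Boltzmann rectification factor
    r(V) = 1 / (1 + exp((V - Vhalf)/k)), monotone decreasing in V, so the
    current at -80 mV is inward (negative) and larger in magnitude than
    at +80 mV.  Units: g in nS, V in mV, I in pA, capacitance in pF.
    """
    from .ephys import RampRecording  # local import to avoid a cycle

    if capacitance <= 0:
        raise ValueError("capacitance must be positive")
    v = np.linspace(v_range[0], v_range[1], n_points)
    r = 1.0 / (1.0 + np.exp((v - rect_vhalf) / rect_slope))
    i = conductance * (v - reversal) * r
    if noise > 0:
        rng = np.random.default_rng(seed)
        i = i + rng.normal(0.0, noise, n_points)
    return RampRecording(voltage=v, current=i, capacitance=capacitance,
                         label=label)
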