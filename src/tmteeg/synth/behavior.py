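"""Generative model of stylus behavior during a TMT trial.

A trial alternates non-linking pauses (stylus resting on the current item with
sub-pixel positional jitter, i.e. near-zero speed) with linking movements
(straight-line travel to the next item under a raised-cosine speed bell:
smooth acceleration to peak speed at the midpoint, then symmetric
deceleration). Non-link pause durations are log-normal, matching the
right-skewed period distributions real performance shows; part B inflates both
link and non-link durations by configurable scales. Occasional errors link to
the wrong (skip-ahead) item and are corrected immediately (... 2 -> 4 -> 3 ...).

The trace is sampled at ~40 Hz with uniformly jittered timestamps and the
trial is truncated at the block duration when incomplete. Ground truth
(linking intervals, non-linking intervals, the scored link sequence) is
returned alongside the trace.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from tmteeg.kinematics import SegmentationResult, StylusTrace
from tmteeg.synth.layout import StimulusLayout

__all__ = [
    "LogNormalSpec",
    "BehaviorSimParams",
    "steady_state_params",
    "simulate_trial_behavior",
    "simulate_perfect_responder",
    "perfect_responder_segmentation",
]


@dataclass(frozen=True)
class LogNormalSpec:
    """Log-normal distribution given as (median, sigma of log)."""

    median: float
    sigma: float

    def draw(self, rng: np.random.Generator, scale: float = 1.0) -> float:
        return float(scale * self.median * np.exp(self.sigma * rng.standard_normal()))


@dataclass(frozen=True)
class BehaviorSimParams:
    """Defaults emulate young-adult tablet TMT performance: sub-second linking
    movements (peak speeds around 550 px/s over typical ~350 px links),
    right-skewed non-link pauses with a ~400 ms median, part-B slowing of 1.25
    on both period types, and rare skip-ahead errors."""

    link_peak_speed_px_s: LogNormalSpec = field(
        default_factory=lambda: LogNormalSpec(550.0, 0.25)
    )
    link_duration_ms: LogNormalSpec | None = None  # overrides speed-based durations
    nonlink_duration_ms: LogNormalSpec = field(
        default_factory=lambda: LogNormalSpec(400.0, 0.6)
    )
    part_b_link_scale: float = 1.25
    part_b_nonlink_scale: float = 1.25
    error_rate: float = 0.02
    sample_rate_hz: float = 40.0
    timestamp_jitter_frac: float = 0.1
    pause_jitter_px: float = 0.15
    min_link_duration_ms: float = 150.0

    def __post_init__(self) -> None:
        if self.part_b_link_scale < 1 or self.part_b_nonlink_scale < 1:
            raise ValueError("part-B scales must be >= 1")
        if not 0.0 <= self.error_rate <= 1.0:
            raise ValueError("error_rate must be in [0, 1]")
        if self.nonlink_duration_ms.median <= 0 or self.sample_rate_hz <= 0:
            raise ValueError("durations and rates must be positive")


def steady_state_params() -> BehaviorSimParams:
    """Quasi-steady-state preset for pipeline calibration.

    Link and non-link periods of a few seconds, long relative to the temporal
    support of 6-cycle wavelets, so that condition-locked amplitude changes can
    be recovered without boundary leakage. Not representative of real TMT
    period durations.
    """
    return BehaviorSimParams(
        link_duration_ms=LogNormalSpec(3000.0, 0.15),
        nonlink_duration_ms=LogNormalSpec(2500.0, 0.15),
        error_rate=0.0,
    )


@dataclass
class _Segment:
    t0: float  # seconds
    t1: float
    kind: str  # "pause" | "link"
    p0: np.ndarray
    p1: np.ndarray


def _hann_displacement(tau: np.ndarray, duration: float) -> np.ndarray:
    """Fraction of the path covered at time tau under a Hann speed bell."""
    u = np.clip(tau / duration, 0.0, 1.0)
    return u - np.sin(2 * np.pi * u) / (2 * np.pi)


def _plan_trial(
    layout: StimulusLayout,
    params: BehaviorSimParams,
    part: str,
    rng: np.random.Generator,
    block_duration_s: float,
) -> tuple[list[_Segment], list[tuple[str, str, bool]]]:
    link_scale = params.part_b_link_scale if part == "B" else 1.0
    nonlink_scale = params.part_b_nonlink_scale if part == "B" else 1.0
    xy = np.array([(s.x, s.y) for s in layout.items])
    labels = [s.label for s in layout.items]
    n = len(labels)

    segments: list[_Segment] = []
    sequence: list[tuple[str, str, bool]] = []
    t = 0.0
    pos_idx = 0  # item index the stylus currently rests on
    progress = 0  # last correctly reached sequence index

    def add_pause(duration: float) -> None:
        nonlocal t
        p = xy[pos_idx]
        segments.append(_Segment(t, t + duration, "pause", p, p))
        t += duration

    def add_link(target_idx: int, correct: bool) -> None:
        nonlocal t, pos_idx
        p0, p1 = xy[pos_idx], xy[target_idx]
        dist = float(np.hypot(*(p1 - p0)))
        if params.link_duration_ms is not None:
            dur = params.link_duration_ms.draw(rng, link_scale) / 1000.0
        else:
            peak = params.link_peak_speed_px_s.draw(rng) / link_scale
            dur = 2.0 * dist / peak
        dur = max(dur, params.min_link_duration_ms / 1000.0)
        segments.append(_Segment(t, t + dur, "link", p0, p1))
        sequence.append((labels[pos_idx], labels[target_idx], correct))
        t += dur
        pos_idx = target_idx

    add_pause(params.nonlink_duration_ms.draw(rng, nonlink_scale) / 1000.0)
    while progress < n - 1 and t < block_duration_s:
        target = progress + 1
        if rng.uniform() < params.error_rate and progress + 2 < n:
            add_link(progress + 2, False)  # skip-ahead error
            if t >= block_duration_s:
                break
            add_pause(params.nonlink_duration_ms.draw(rng, nonlink_scale) / 1000.0)
            if t >= block_duration_s:
                break
        add_link(target, True)
        progress = target
        if progress < n - 1 and t < block_duration_s:
            add_pause(params.nonlink_duration_ms.draw(rng, nonlink_scale) / 1000.0)
    return segments, sequence


def _sample_trace(
    segments: list[_Segment],
    params: BehaviorSimParams,
    rng: np.random.Generator,
    completion_s: float,
) -> StylusTrace:
    dt_nom = 1.0 / params.sample_rate_hz
    n_draw = int(completion_s * params.sample_rate_hz * 1.2) + 16
    dts = dt_nom * (
        1.0 + rng.uniform(-1, 1, size=n_draw) * params.timestamp_jitter_frac
    )
    ts = np.concatenate([[0.0], np.cumsum(dts)])
    while ts[-1] <= completion_s:  # pragma: no cover - jitter margin exceeded
        extra = dt_nom * (
            1.0 + rng.uniform(-1, 1, size=16) * params.timestamp_jitter_frac
        )
        ts = np.concatenate([ts, ts[-1] + np.cumsum(extra)])
    ts = ts[ts <= completion_s]
    x = np.empty_like(ts)
    y = np.empty_like(ts)
    bounds = np.array([s.t0 for s in segments] + [segments[-1].t1])
    idx = np.clip(np.searchsorted(bounds, ts, side="right") - 1, 0, len(segments) - 1)
    for i, seg in enumerate(segments):
        sel = idx == i
        if not sel.any():
            continue
        tau = ts[sel] - seg.t0
        if seg.kind == "pause":
            jit = rng.normal(0.0, params.pause_jitter_px, size=(sel.sum(), 2))
            x[sel] = seg.p0[0] + jit[:, 0]
            y[sel] = seg.p0[1] + jit[:, 1]
        else:
            frac = _hann_displacement(tau, seg.t1 - seg.t0)
            x[sel] = seg.p0[0] + frac * (seg.p1[0] - seg.p0[0])
            y[sel] = seg.p0[1] + frac * (seg.p1[1] - seg.p0[1])
    return StylusTrace(ts * 1000.0, x, y, np.ones(ts.size, dtype=int))


def _truth_segmentation(
    segments: list[_Segment], completion_s: float
) -> SegmentationResult:
    link, nonlink = [], []
    for seg in segments:
        a = min(seg.t0, completion_s) * 1000.0
        b = min(seg.t1, completion_s) * 1000.0
        if b <= a:
            continue
        (link if seg.kind == "link" else nonlink).append((a, b))
    return SegmentationResult(link, nonlink, float("nan"), len(link))


def simulate_trial_behavior(
    layout: StimulusLayout,
    params: BehaviorSimParams,
    part: str,
    rng: np.random.Generator,
    block_duration_s: float,
) -> tuple[StylusTrace, SegmentationResult, list[tuple[str, str, bool]]]:
    """Simulate one trial; returns (trace, ground-truth segmentation, link
    sequence as (source_label, target_label, correct) triples).

    Truncation at the block duration is legal behavior: the ground-truth
    intervals are clipped to the performed duration and the link sequence
    keeps only links that started before the cutoff.
    """
    if layout.part != part:
        raise ValueError(f"layout is part {layout.part}, requested {part}")
    segments, sequence = _plan_trial(layout, params, part, rng, block_duration_s)
    completion = min(segments[-1].t1, block_duration_s)
    # a link fragment too short to score at the cutoff ends the analyzed trial
    # just before it, so ground truth and scorable links stay consistent
    min_link_s = params.min_link_duration_ms / 1000.0
    for seg in segments:
        if seg.kind == "link" and seg.t0 < completion < seg.t1:
            if completion - seg.t0 < min_link_s:
                completion = seg.t0
    n_started_links = sum(
        1 for s in segments if s.kind == "link" and s.t0 < completion
    )
    sequence = sequence[:n_started_links]
    trace = _sample_trace(segments, params, rng, completion)
    truth = _truth_segmentation(segments, completion)
    return trace, truth, sequence


def simulate_perfect_responder(
    layout: StimulusLayout,
    constant_speed_px_s: float,
    sample_rate_hz: float = 40.0,
) -> StylusTrace:
    """Idealized responder: no pauses, no errors, piecewise-linear motion from
    item to item at constant speed. Total duration = path length / speed."""
    if constant_speed_px_s <= 0:
        raise ValueError("constant_speed must be positive")
    xy = np.array([(s.x, s.y) for s in layout.items])
    leg = np.hypot(*np.diff(xy, axis=0).T)
    cum_t = np.concatenate([[0.0], np.cumsum(leg / constant_speed_px_s)])
    total = cum_t[-1]
    ts = np.arange(0.0, total, 1.0 / sample_rate_hz)
    ts = np.append(ts, total)
    x = np.interp(ts, cum_t, xy[:, 0])
    y = np.interp(ts, cum_t, xy[:, 1])
    return StylusTrace(ts * 1000.0, x, y, np.ones(ts.size, dtype=int))


def perfect_responder_segmentation(
    layout: StimulusLayout, constant_speed_px_s: float
) -> SegmentationResult:
    """Ground-truth segmentation of a perfect responder: 24 back-to-back
    linking intervals at item arrival times, no non-linking intervals."""
    xy = np.array([(s.x, s.y) for s in layout.items])
    leg = np.hypot(*np.diff(xy, axis=0).T)
    cum_t = np.concatenate([[0.0], np.cumsum(leg / constant_speed_px_s)]) * 1000.0
    link = [(float(a), float(b)) for a, b in zip(cum_t[:-1], cum_t[1:])]
    return SegmentationResult(link, [], float("nan"), len(link))
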