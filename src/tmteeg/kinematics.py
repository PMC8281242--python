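"""Stylus kinematics: speed estimation, smoothing, segmentation and scoring.

The tablet logs stylus position at ~40 Hz. This module turns those logs into
speed time-courses, splits each trial into *linking* periods (rapid, purposeful
movements connecting two stimuli) and *non-linking* periods (visual search and
motor planning at near-zero speed), scores the resulting link sequence against
the stimulus order, and computes per-trial behavioral metrics, most importantly
the seconds-per-link (SPL) score used for block designs with fixed trial
duration.

Processing order: finite-difference speed -> sigma filter (spike removal) ->
5 Hz zero-phase low-pass -> cubic-spline resampling to 1000 Hz -> threshold
segmentation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from scipy.signal import butter, sosfiltfilt

logger = logging.getLogger(__name__)

__all__ = [
    "StylusTrace",
    "SpeedSeries",
    "SegmentationResult",
    "LinkEvent",
    "TrialKinematics",
    "DataError",
    "SegmentationError",
    "read_stylus_tsv",
    "compute_speed",
    "sigma_filter",
    "lowpass_and_resample",
    "segment_by_threshold",
    "extract_links",
    "compute_trial_metrics",
]


class DataError(ValueError):
    """Raised when an input trace or series violates a precondition."""


class SegmentationError(RuntimeError):
    """No threshold on the step grid produced the expected link count."""

    def __init__(self, expected: int, achievable: set[int]):
        self.expected = expected
        self.achievable = achievable
        super().__init__(
            f"no threshold yields {expected} linking periods; "
            f"achievable counts: {sorted(achievable)}"
        )


@dataclass
class StylusTrace:
    """Timestamped pen positions for one trial.

    t_ms is strictly increasing; coordinates are pixels with the origin at the
    top-left of the display (x right, y down); pen_down is 1 while the stylus
    touches the surface.
    """

    t_ms: np.ndarray
    x_px: np.ndarray
    y_px: np.ndarray
    pen_down: np.ndarray

    def __post_init__(self) -> None:
        self.t_ms = np.asarray(self.t_ms, dtype=float)
        self.x_px = np.asarray(self.x_px, dtype=float)
        self.y_px = np.asarray(self.y_px, dtype=float)
        self.pen_down = np.asarray(self.pen_down, dtype=int)
        if self.t_ms.size < 2:
            raise DataError("trace needs at least 2 samples")
        if np.any(np.diff(self.t_ms) <= 0):
            raise DataError("timestamps must be strictly increasing")
        if not (np.isfinite(self.x_px).all() and np.isfinite(self.y_px).all()):
            raise DataError("coordinates must be finite")

    @property
    def n_samples(self) -> int:
        return self.t_ms.size

    @property
    def duration_ms(self) -> float:
        return float(self.t_ms[-1] - self.t_ms[0])


@dataclass
class SpeedSeries:
    """Speed (px/s) versus time (ms). Uniform 1 ms spacing after resampling."""

    t_ms: np.ndarray
    v_px_s: np.ndarray

    def __post_init__(self) -> None:
        self.t_ms = np.asarray(self.t_ms, dtype=float)
        self.v_px_s = np.asarray(self.v_px_s, dtype=float)
        if self.t_ms.shape != self.v_px_s.shape:
            raise DataError("t and v must have equal length")

    @property
    def native_dt_ms(self) -> float:
        return float(np.median(np.diff(self.t_ms)))


@dataclass
class SegmentationResult:
    """Half-open linking / non-linking intervals plus the threshold used.

    Intervals are [start_ms, end_ms) relative to trial onset; their union is
    [0, completion_ms) and they are disjoint and ordered.
    """

    linking_intervals: list[tuple[float, float]]
    nonlinking_intervals: list[tuple[float, float]]
    threshold_px_s: float
    n_links_found: int = field(default=-1)

    def __post_init__(self) -> None:
        if self.n_links_found < 0:
            self.n_links_found = len(self.linking_intervals)

    @property
    def completion_ms(self) -> float:
        ends = [iv[1] for iv in self.linking_intervals + self.nonlinking_intervals]
        return max(ends) if ends else 0.0

    def linking_mask(self, n_ms: int | None = None) -> np.ndarray:
        """Boolean mask at 1 ms resolution from trial onset."""
        n = int(round(self.completion_ms)) if n_ms is None else n_ms
        mask = np.zeros(n, dtype=bool)
        for a, b in self.linking_intervals:
            mask[int(round(a)) : int(round(b))] = True
        return mask


@dataclass
class LinkEvent:
    start_ms: float
    end_ms: float
    mean_speed_px_s: float
    source_label: str | None
    target_label: str | None
    correct: bool
    resolved: bool = True


@dataclass
class TrialKinematics:
    completion_time_s: float
    n_errors: int
    n_total_links: int
    n_correct_links: int
    spl_s: float
    linking_period_ms: list[float]
    nonlinking_period_ms: list[float]
    avg_link_speed_px_s: list[float]


def read_stylus_tsv(path: str | Path) -> StylusTrace:
    df = pd.read_csv(path, sep="\t", comment="#")
    return StylusTrace(
        df["t_ms"].to_numpy(),
        df["x_px"].to_numpy(),
        df["y_px"].to_numpy(),
        df["pen_down"].to_numpy(),
    )


def compute_speed(trace: StylusTrace) -> SpeedSeries:
    """Finite-difference speed at the native rate.

    v_i = sqrt(dx^2 + dy^2) / dt for each consecutive sample pair, assigned to
    the midpoint time. Pairs that span a pen lift are set to zero so that the
    gap interior is counted as non-linking time.
    """
    dt = np.diff(trace.t_ms)
    if np.any(dt == 0):
        raise DataError("duplicate timestamps")
    dx = np.diff(trace.x_px)
    dy = np.diff(trace.y_px)
    v = np.hypot(dx, dy) / (dt / 1000.0)
    down = (trace.pen_down[:-1] > 0) & (trace.pen_down[1:] > 0)
    v = np.where(down, v, 0.0)
    t_mid = trace.t_ms[:-1] + dt / 2.0
    return SpeedSeries(t_mid, v)


def _window_bounds(t: np.ndarray, half_ms: float) -> tuple[np.ndarray, np.ndarray]:
    lo = np.searchsorted(t, t - half_ms, side="left")
    hi = np.searchsorted(t, t + half_ms, side="right")
    return lo, hi


def sigma_filter(series: SpeedSeries, window_ms: float = 151.0, k_sd: float = 2.0) -> SpeedSeries:
    """Sliding-window outlier smoother.

    Within the centered time window around each sample the mean and SD are
    computed; samples farther than ``k_sd`` SDs from the window mean are
    replaced by the average of the window's non-outlier values. If a window has
    no non-outliers the window median is used instead (logged).
    """
    t, v = series.t_ms, series.v_px_s
    lo, hi = _window_bounds(t, window_ms / 2.0)
    if np.min(hi - lo) < 3:
        raise DataError("sigma filter window covers fewer than 3 samples")
    c1 = np.concatenate([[0.0], np.cumsum(v)])
    c2 = np.concatenate([[0.0], np.cumsum(v * v)])
    n = (hi - lo).astype(float)
    mean = (c1[hi] - c1[lo]) / n
    var = np.maximum((c2[hi] - c2[lo]) / n - mean**2, 0.0)
    sd = np.sqrt(var)
    is_out = np.abs(v - mean) > k_sd * sd
    out = v.copy()
    for i in np.flatnonzero(is_out):
        w = v[lo[i] : hi[i]]
        keep = np.abs(w - mean[i]) <= k_sd * sd[i]
        if keep.any():
            out[i] = w[keep].mean()
        else:  # pragma: no cover - requires pathological window
            logger.warning("sigma filter: empty non-outlier set at t=%.1f ms", t[i])
            out[i] = np.median(w)
    return SpeedSeries(t, out)


def lowpass_and_resample(
    series: SpeedSeries,
    cutoff_hz: float = 5.0,
    out_rate_hz: float = 1000.0,
    order: int = 4,
) -> SpeedSeries:
    """Zero-phase low-pass then cubic-spline resampling to a uniform grid.

    The low-pass is a 4th-order Butterworth applied forward-backward at the
    native (median) rate, so interval boundaries suffer no phase shift.
    Negative interpolation artifacts are clipped to zero.
    """
    t, v = series.t_ms, series.v_px_s
    fs = 1000.0 / series.native_dt_ms
    sos = butter(order, cutoff_hz, btype="low", fs=fs, output="sos")
    padlen = 3 * (2 * sos.shape[0] + 1)
    if v.size <= padlen:
        raise DataError(f"series too short for zero-phase filter (need >{padlen} samples)")
    filt = sosfiltfilt(sos, v)
    dt_out = 1000.0 / out_rate_hz
    grid = np.arange(t[0], t[-1] + dt_out / 2, dt_out)
    resampled = CubicSpline(t, filt)(grid)
    return SpeedSeries(grid, np.maximum(resampled, 0.0))


def _intervals_from_mask(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    d = np.diff(mask.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1) + 1
    if mask[0]:
        starts = np.concatenate([[0], starts])
    if mask[-1]:
        ends = np.concatenate([ends, [mask.size]])
    return starts, ends


def _excursions(
    v: np.ndarray, threshold: float, min_dur: int, merge_gap: int
) -> tuple[np.ndarray, np.ndarray]:
    mask = v >= threshold
    if not mask.any():
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    starts, ends = _intervals_from_mask(mask)
    if starts.size > 1 and merge_gap > 0:
        gaps = starts[1:] - ends[:-1]
        keep = gaps >= merge_gap
        starts = np.concatenate([[starts[0]], starts[1:][keep]])
        ends = np.concatenate([ends[:-1][keep], [ends[-1]]])
    if min_dur > 0:
        long_enough = (ends - starts) >= min_dur
        starts, ends = starts[long_enough], ends[long_enough]
    return starts, ends


def segment_by_threshold(
    speed: SpeedSeries,
    expected_links: int,
    step_px_s: float = 1.0,
    min_duration_ms: float = 50.0,
    merge_gap_ms: float = 20.0,
    stability_steps: int = 5,
) -> SegmentationResult:
    """Find the smallest speed threshold producing the expected link count.

    The candidate threshold rises from 0 px/s in constant steps; at each step
    the supra-threshold excursions (gaps under ``merge_gap_ms`` merged,
    excursions under ``min_duration_ms`` dropped) are counted, until the count
    equals the number of links known from scoring. A match must persist for
    ``stability_steps`` consecutive steps — the automated counterpart of
    requiring that linking periods be readily identifiable rather than an
    accidental count match inside the pause-noise band. The accepted
    threshold therefore exceeds the peak speed of the fastest non-linking
    excursion.
    """
    if expected_links < 1:
        raise ValueError("expected_links must be >= 1")
    v = speed.v_px_s
    dt = speed.native_dt_ms
    min_dur = max(int(round(min_duration_ms / dt)), 1)
    merge_gap = int(round(merge_gap_ms / dt))
    vmax = float(v.max())
    achievable: set[int] = set()
    thr = step_px_s
    candidate: tuple[float, np.ndarray, np.ndarray] | None = None
    fallback: tuple[float, np.ndarray, np.ndarray] | None = None
    streak = 0
    found: tuple[float, np.ndarray, np.ndarray] | None = None
    while thr <= vmax + step_px_s:
        starts, ends = _excursions(v, thr, min_dur, merge_gap)
        n = starts.size
        achievable.add(n)
        if n == expected_links:
            if candidate is None:
                candidate = (thr, starts, ends)
            if fallback is None:
                fallback = (thr, starts, ends)
            streak += 1
            if streak >= stability_steps:
                found = candidate
                break
        else:
            candidate = None
            streak = 0
        thr += step_px_s
    if found is None and fallback is not None:
        # no stable plateau; accept the smallest exact-count match
        logger.warning(
            "threshold count match for %d links never stable over %d steps; "
            "using smallest match %.1f px/s",
            expected_links, stability_steps, fallback[0],
        )
        found = fallback
    if found is None:
        raise SegmentationError(expected_links, achievable)
    thr_found, starts, ends = found
    t0 = speed.t_ms[0]
    link = [
        (speed.t_ms[s] - t0, speed.t_ms[e - 1] + dt - t0)
        for s, e in zip(starts, ends)
    ]
    total = speed.t_ms[-1] + dt - t0
    nonlink = []
    prev = 0.0
    for a, b in link:
        if a > prev:
            nonlink.append((prev, a))
        prev = b
    if total > prev:
        nonlink.append((prev, total))
    return SegmentationResult(link, nonlink, thr_found, expected_links)


def _position_at(trace: StylusTrace, t_ms: float) -> tuple[float, float]:
    x = float(np.interp(t_ms, trace.t_ms, trace.x_px))
    y = float(np.interp(t_ms, trace.t_ms, trace.y_px))
    return x, y


def extract_links(
    segmentation: SegmentationResult,
    trace: StylusTrace,
    layout,
    capture_factor: float = 1.5,
) -> list[LinkEvent]:
    """Score each linking interval against the stimulus sequence.

    The target of a link is the stimulus nearest to the stylus position at the
    interval end, within ``capture_factor`` times the stimulus radius; items
    merely crossed mid-link (no segmentation boundary there) are ignored. A
    link is correct iff its target is the sequence successor of the current
    progress; an error does not advance progress, so a corrective link back to
    the proper successor is scored correct (e.g. 2 -> 4 -> 3).
    """
    items = layout.items
    xy = np.array([(it.x, it.y) for it in items])
    radius = np.array([it.r for it in items])
    t0 = trace.t_ms[0]
    progress = 0  # index of last correctly reached item
    prev_label: str | None = items[0].label
    events: list[LinkEvent] = []
    for a, b in segmentation.linking_intervals:
        px, py = _position_at(trace, t0 + b)
        d = np.hypot(xy[:, 0] - px, xy[:, 1] - py)
        nearest = int(np.argmin(d))
        resolved = d[nearest] <= capture_factor * radius[nearest]
        # mean speed over the interval from the raw trace path
        sel = (trace.t_ms - t0 >= a) & (trace.t_ms - t0 <= b)
        if sel.sum() >= 2:
            path = float(
                np.sum(np.hypot(np.diff(trace.x_px[sel]), np.diff(trace.y_px[sel])))
            )
            mean_speed = path / ((b - a) / 1000.0)
        else:  # pragma: no cover - sub-sample interval
            mean_speed = 0.0
        if resolved:
            target = items[nearest].label
            correct = nearest == progress + 1
            if correct:
                progress += 1
            events.append(
                LinkEvent(a, b, mean_speed, prev_label, target, correct, True)
            )
            prev_label = target
        else:
            events.append(
                LinkEvent(a, b, mean_speed, prev_label, None, False, False)
            )
    return events


def compute_trial_metrics(
    segmentation: SegmentationResult,
    links: list[LinkEvent],
    block_duration_s: float,
    n_items: int = 25,
) -> TrialKinematics:
    """Per-trial metrics including the seconds-per-link (SPL) score.

    SPL divides the completion time by the number of correct links; the
    completion time is the end of the final link when the trial was finished
    (all ``n_items - 1`` correct links), else the block duration.
    """
    n_correct = sum(1 for e in links if e.correct)
    if n_correct == 0:
        raise DataError("SPL undefined: zero correct links")
    n_total = len(links)
    complete = n_correct == n_items - 1
    completion_s = links[-1].end_ms / 1000.0 if complete else block_duration_s
    return TrialKinematics(
        completion_time_s=completion_s,
        n_errors=n_total - n_correct,
        n_total_links=n_total,
        n_correct_links=n_correct,
        spl_s=completion_s / n_correct,
        linking_period_ms=[b - a for a, b in segmentation.linking_intervals],
        nonlinking_period_ms=[b - a for a, b in segmentation.nonlinking_intervals],
        avg_link_speed_px_s=[e.mean_speed_px_s for e in links],
    )
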