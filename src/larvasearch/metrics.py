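"""Per-phase trajectory metrics and the search score.

All metrics operate on a repaired (gap-free, mm-unit) track restricted
to a half-open time window [t0, t1).  The arena is divided into seven
radial distance categories (0-4, 4-8, ..., 20-24, >24 mm) which collapse
pairwise into four zones: center (0-8), search (8-16), neutral (16-24)
and edge (>24 mm).  Binning is half-open [lo, hi), so a larva exactly on
a boundary belongs to the outer category.

The search score condenses a phase into one preference number:

    score = (time in search zone - time in edge zone) / analyzed time

so +1 means the larva spent the whole phase circling at 8-16 mm from
the center (pure search-zone residency) and -1 means it hugged the wall
throughout.

Dwell accounting is per frame: each frame contributes 1/frame_rate
seconds to the category of its own radial position (no splitting of the
step across a boundary; at 2 frames/s the error is at most half a
second per transition).  Track length attributes each step to the
category of its starting frame; steps into or out of frames whose
position is unknown (edge-assigned) contribute no length.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import CATEGORY_TO_ZONE, N_CATEGORIES, ZONES, ArenaConfig
from .repair import RepairedTrack

__all__ = [
    "PhaseMetrics",
    "SpeedSeries",
    "window_mask",
    "category_of",
    "zone_of",
    "dwell_times",
    "zone_times",
    "track_length",
    "speed_series",
    "count_revisits",
    "count_stops",
    "minute_bins",
    "search_score",
    "compute_phase_metrics",
]


def window_mask(track: RepairedTrack, window: tuple[float, float]) -> np.ndarray:
    """Boolean mask of frames with t0 <= t_s < t1."""
    t0, t1 = window
    return (track.t_s >= t0) & (track.t_s < t1)


def category_of(r_mm, edges=(4.0, 8.0, 12.0, 16.0, 20.0, 24.0)):
    """Distance category index 0..6 for radius r (half-open bins)."""
    return np.searchsorted(np.asarray(edges), np.asarray(r_mm), side="right")


def zone_of(r_mm, edges=(4.0, 8.0, 12.0, 16.0, 20.0, 24.0)):
    """Zone index 0..3 (center/search/neutral/edge) for radius r."""
    cat = category_of(r_mm, edges)
    return np.asarray(CATEGORY_TO_ZONE)[cat]


def dwell_times(
    track: RepairedTrack,
    window: tuple[float, float],
    edges: tuple[float, ...] = (4.0, 8.0, 12.0, 16.0, 20.0, 24.0),
) -> np.ndarray:
    """Seconds spent in each of the seven distance categories."""
    m = window_mask(track, window)
    cat = category_of(track.r_mm[m], edges)
    return np.bincount(cat, minlength=N_CATEGORIES) / track.frame_rate


def zone_times(time_per_category_s: np.ndarray) -> np.ndarray:
    """Collapse the seven category dwell times into the four zones."""
    t = np.asarray(time_per_category_s, dtype=float)
    return np.array([t[0] + t[1], t[2] + t[3], t[4] + t[5], t[6]])


def _step_lengths(track: RepairedTrack, m: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Step lengths between consecutive in-window frames and a validity mask.

    Steps touching an edge-assigned frame (unknown position) are invalid.
    """
    idx = np.flatnonzero(m)
    if idx.size < 2:
        return np.zeros(0), np.zeros(0, dtype=bool)
    sl = slice(idx[0], idx[-1] + 1)
    dx = np.diff(track.x_mm[sl])
    dy = np.diff(track.y_mm[sl])
    steps = np.hypot(dx, dy)
    valid = ~np.isnan(steps)
    return steps, valid


def track_length(
    track: RepairedTrack,
    window: tuple[float, float],
    edges: tuple[float, ...] = (4.0, 8.0, 12.0, 16.0, 20.0, 24.0),
) -> tuple[float, np.ndarray]:
    """Cumulated path length in mm, total and attributed per category.

    Consecutive-coordinate distances are summed; each step counts toward
    the distance category of its starting frame.
    """
    m = window_mask(track, window)
    steps, valid = _step_lengths(track, m)
    per_cat = np.zeros(N_CATEGORIES)
    if steps.size == 0:
        return 0.0, per_cat
    idx = np.flatnonzero(m)
    start_r = track.r_mm[idx[0] : idx[-1] + 1][:-1]
    cat = category_of(start_r[valid], edges)
    np.add.at(per_cat, cat, steps[valid])
    return float(np.sum(steps[valid])), per_cat


@dataclass
class SpeedSeries:
    """Instantaneous and 10-frame-smoothed speed over a window."""

    t_s: np.ndarray  # time of each step start
    instantaneous_mm_s: np.ndarray
    smoothed_mm_s: np.ndarray  # moving average, aligned to t_smooth_s
    t_smooth_s: np.ndarray
    median_mm_s: float


def speed_series(
    track: RepairedTrack,
    window: tuple[float, float],
    avg_frames: int = 10,
) -> SpeedSeries:
    """Per-step crawling speed (step length x frame rate) plus summaries.

    The plotted trace is a moving average over ``avg_frames`` frames;
    the scalar summary is the median instantaneous speed.  Steps with
    unknown positions are dropped.
    """
    m = window_mask(track, window)
    steps, valid = _step_lengths(track, m)
    if steps.size == 0:
        empty = np.zeros(0)
        return SpeedSeries(empty, empty, empty, empty, float("nan"))
    idx = np.flatnonzero(m)
    t = track.t_s[idx[0] : idx[-1] + 1][:-1]
    v = steps[valid] * track.frame_rate
    tv = t[valid]
    if v.size >= avg_frames:
        kernel = np.ones(avg_frames) / avg_frames
        smooth = np.convolve(v, kernel, mode="valid")
        ts = tv[avg_frames - 1 :]
    else:
        smooth = np.array([np.mean(v)])
        ts = tv[-1:]
    return SpeedSeries(tv, v, smooth, ts, float(np.median(v)))


def count_revisits(
    track: RepairedTrack,
    window: tuple[float, float],
    center_zone_radius_mm: float = 8.0,
) -> int:
    """Inward crossings of the center-zone border.

    A revisit is a frame pair with r_i > radius and r_{i+1} <= radius
    (landing exactly on the border counts as entering).  Starting inside
    the zone does not count.
    """
    m = window_mask(track, window)
    r = track.r_mm[m]
    if r.size < 2:
        return 0
    inside = r <= center_zone_radius_mm
    return int(np.count_nonzero(~inside[:-1] & inside[1:]))


def count_stops(
    track: RepairedTrack,
    window: tuple[float, float],
    stop_displacement_mm: float = 0.05,
    stop_window_frames: int = 5,
) -> tuple[int, list[tuple[int, int]]]:
    """Count stop episodes and return their step-index intervals.

    A stop begins at the first step shorter than the displacement
    threshold.  It ends only once the larva has moved continuously —
    every one of the next ``stop_window_frames`` steps at or above the
    threshold.  Stop episodes separated by ``stop_window_frames`` or
    fewer moving frames are merged and counted once.

    Returns ``(n_stops, intervals)`` where each interval is the
    (first, last) sub-threshold step index of a merged stop, relative to
    the window start.
    """
    m = window_mask(track, window)
    steps, valid = _step_lengths(track, m)
    if steps.size == 0:
        return 0, []
    sub = valid & (steps < stop_displacement_mm)

    # raw episodes: a stop is open until `stop_window_frames` consecutive
    # moving steps are seen
    raw: list[tuple[int, int]] = []
    in_stop = False
    start = last_sub = 0
    moving_run = 0
    for i, s in enumerate(sub):
        if s:
            if not in_stop:
                in_stop = True
                start = i
            last_sub = i
            moving_run = 0
        elif in_stop:
            moving_run += 1
            if moving_run >= stop_window_frames:
                raw.append((start, last_sub))
                in_stop = False
    if in_stop:
        raw.append((start, last_sub))

    # merge episodes separated by <= stop_window_frames steps
    merged: list[tuple[int, int]] = []
    for ivl in raw:
        if merged and ivl[0] - merged[-1][1] - 1 <= stop_window_frames:
            merged[-1] = (merged[-1][0], ivl[1])
        else:
            merged.append(ivl)
    return len(merged), merged


def minute_bins(
    track: RepairedTrack,
    window: tuple[float, float],
    bin_s: float = 60.0,
) -> list[dict]:
    """Mean distance to center in consecutive 1 min bins of the window.

    A trailing partial bin is reported with its actual duration.
    """
    t0, t1 = window
    out = []
    b0 = t0
    while b0 < t1 - 1e-9:
        b1 = min(b0 + bin_s, t1)
        m = (track.t_s >= b0) & (track.t_s < b1)
        r = track.r_mm[m]
        out.append(
            {
                "bin_start_s": b0,
                "duration_s": b1 - b0,
                "mean_r_mm": float(np.mean(r)) if r.size else float("nan"),
                "n_frames": int(r.size),
            }
        )
        b0 = b1
    return out


def search_score(time_per_zone_s, total_time_s: float) -> float:
    """(time in search zone - time in edge zone) / total analyzed time.

    Positive values indicate a search-zone preference, negative values
    an edge preference; bounded in [-1, 1].
    """
    if total_time_s <= 0:
        raise ValueError("total_time_s must be positive")
    t = np.asarray(time_per_zone_s, dtype=float)
    return float((t[1] - t[3]) / total_time_s)


@dataclass
class PhaseMetrics:
    """All scalar and binned metrics for one larva in one phase."""

    larva_id: str
    phase: str
    window: tuple[float, float]
    median_r_mm: float
    r_per_minute_mm: list[dict]
    time_per_category_s: np.ndarray
    time_per_zone_s: np.ndarray
    length_per_category_mm: np.ndarray
    total_length_mm: float
    median_speed_mm_s: float
    time_in_center_zone_s: float
    n_revisits: int
    n_stops: int
    search_score: float

    def scalar_row(self) -> dict:
        """Tidy-table row of the scalar metrics."""
        row = {
            "larva_id": self.larva_id,
            "phase": self.phase,
            "t0_s": self.window[0],
            "t1_s": self.window[1],
            "median_r_mm": self.median_r_mm,
            "total_length_mm": self.total_length_mm,
            "median_speed_mm_s": self.median_speed_mm_s,
            "time_in_center_zone_s": self.time_in_center_zone_s,
            "n_revisits": self.n_revisits,
            "n_stops": self.n_stops,
            "search_score": self.search_score,
        }
        for i, z in enumerate(ZONES):
            row[f"time_{z}_s"] = float(self.time_per_zone_s[i])
        for i in range(N_CATEGORIES):
            row[f"time_cat{i}_s"] = float(self.time_per_category_s[i])
            row[f"length_cat{i}_mm"] = float(self.length_per_category_mm[i])
        return row


def compute_phase_metrics(
    track: RepairedTrack,
    window: tuple[float, float],
    phase: str,
    config: ArenaConfig,
) -> PhaseMetrics:
    """Compute every per-phase metric for one larva in one window."""
    edges = config.zone_edges_mm
    m = window_mask(track, window)
    r = track.r_mm[m]
    tpc = dwell_times(track, window, edges)
    tpz = zone_times(tpc)
    total_len, len_per_cat = track_length(track, window, edges)
    speeds = speed_series(track, window)
    n_stops, _ = count_stops(
        track, window, config.stop_displacement_mm, config.stop_window_frames
    )
    duration = window[1] - window[0]
    return PhaseMetrics(
        larva_id=track.larva_id,
        phase=phase,
        window=window,
        median_r_mm=float(np.median(r)) if r.size else float("nan"),
        r_per_minute_mm=minute_bins(track, window),
        time_per_category_s=tpc,
        time_per_zone_s=tpz,
        length_per_category_mm=len_per_cat,
        total_length_mm=total_len,
        median_speed_mm_s=speeds.median_mm_s,
        time_in_center_zone_s=float(tpz[0]),
        n_revisits=count_revisits(track, window, config.center_zone_radius_mm),
        n_stops=n_stops,
        search_score=search_score(tpz, duration) if duration > 0 else float("nan"),
    )
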