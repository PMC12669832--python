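"""Gap classification and interpolation for larval centroid tracks.

Detection failures leave runs of missing frames in a raw track.  Each
maximal missing run is assigned exactly one repair class, in priority
order:

1. ``end_hold`` — the gap runs to the end of the recording: the last
   tracked coordinate is repeated.
2. ``container_contact`` — both flanking positions lie within the
   container-proximity radius while the container is in the arena: the
   larva is hidden at the container, so the entry position is held.
3. ``arc`` — both flanking positions are near the arena edge (beyond
   the edge-gap threshold): the larva was wall-following, and the gap
   is filled along a circular path about the arena center.
4. ``edge_assigned`` — the flanking frames carry the visually verified
   wall flag: only edge-zone membership is known, so frames get the
   nominal edge-zone radius and no x/y position.
5. ``linear`` — everything else: straight-line interpolation.

The arc follows the minor (shorter) angular path, with the radius
blended linearly between the flanking radii; near-antipodal flanks fall
back to a straight line (a 180-degree arc direction would be arbitrary).
Coordinates are converted to millimetres relative to the arena center,
and every frame carries its provenance.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .config import ArenaConfig
from .io import EventLog, RawTrack

logger = logging.getLogger(__name__)

__all__ = [
    "GapSpec",
    "RepairedTrack",
    "find_gaps",
    "classify_gap",
    "interpolate_linear",
    "interpolate_arc",
    "repair_track",
]

PROVENANCE_CLASSES = (
    "observed",
    "linear",
    "arc",
    "held",
    "edge_assigned",
    "container_contact",
)

ANTIPODAL_TOL_RAD = 1e-9


@dataclass(frozen=True)
class GapSpec:
    """A maximal run of missing frames, as dense-array index positions."""

    start: int  # first missing index
    stop: int  # last missing index (inclusive)

    @property
    def k(self) -> int:
        return self.stop - self.start + 1


@dataclass
class RepairedTrack:
    """Gap-free trajectory in mm with per-frame provenance.

    ``x_mm``/``y_mm`` are relative to the arena center; they are NaN for
    ``edge_assigned`` frames, whose exact position is unknown but whose
    radial distance is pinned to the edge-zone midpoint.
    """

    larva_id: str
    frames: np.ndarray
    t_s: np.ndarray
    x_mm: np.ndarray
    y_mm: np.ndarray
    r_mm: np.ndarray
    provenance: np.ndarray
    frame_rate: float

    @property
    def n_frames(self) -> int:
        return int(self.frames.size)


def find_gaps(track: RawTrack) -> list[GapSpec]:
    """Locate maximal missing runs in a raw track."""
    miss = track.missing_mask
    gaps: list[GapSpec] = []
    i = 0
    n = miss.size
    while i < n:
        if miss[i]:
            j = i
            while j + 1 < n and miss[j + 1]:
                j += 1
            gaps.append(GapSpec(i, j))
            i = j + 1
        else:
            i += 1
    return gaps


def _radius_mm(track: RawTrack, idx: int, config: ArenaConfig) -> float:
    dx = (track.x_px[idx] - config.center_x_px) * config.px_to_mm
    dy = (track.y_px[idx] - config.center_y_px) * config.px_to_mm
    return math.hypot(dx, dy)


def classify_gap(
    track: RawTrack,
    gap: GapSpec,
    config: ArenaConfig,
    events: EventLog | None = None,
) -> str:
    """Assign one repair class to a missing run (see module docstring)."""
    if gap.start == 0:
        raise ValueError(f"track {track.larva_id!r} starts with missing frames")
    if gap.stop == track.n_frames - 1:
        return "end_hold"
    before, after = gap.start - 1, gap.stop + 1
    r_before = _radius_mm(track, before, config)
    r_after = _radius_mm(track, after, config)

    if events is not None and not events.excluded:
        t0 = track.frames[gap.start] / config.frame_rate
        t1 = (track.frames[gap.stop] + 1) / config.frame_rate
        container_present = (
            events.t_container_removed is not None
            and t1 > events.t_container_placed
            and t0 < events.t_container_removed
        )
        near = config.container_proximity_radius_mm
        if container_present and r_before <= near and r_after <= near:
            return "container_contact"

    if r_before > config.edge_gap_threshold_mm and r_after > config.edge_gap_threshold_mm:
        return "arc"
    if track.edge_flag[before] and track.edge_flag[after]:
        return "edge_assigned"
    return "linear"


def interpolate_linear(
    p_before: Sequence[float], p_after: Sequence[float], k_missing: int
) -> np.ndarray:
    """``k_missing`` evenly spaced points strictly between two positions."""
    if k_missing < 1:
        raise ValueError("k_missing must be >= 1")
    t = np.arange(1, k_missing + 1) / (k_missing + 1)
    p0 = np.asarray(p_before, dtype=float)
    p1 = np.asarray(p_after, dtype=float)
    return p0 + t[:, None] * (p1 - p0)


def interpolate_arc(
    p_before: Sequence[float],
    p_after: Sequence[float],
    k_missing: int,
    center: Sequence[float],
) -> np.ndarray:
    """Points along the minor circular arc about ``center``.

    Angles are evenly spaced along the shorter angular path from
    ``p_before`` to ``p_after``; the radius is blended linearly between
    the two flanking radii.  Raises ValueError for antipodal flanks
    (callers fall back to straight-line interpolation).
    """
    if k_missing < 1:
        raise ValueError("k_missing must be >= 1")
    c = np.asarray(center, dtype=float)
    v0 = np.asarray(p_before, dtype=float) - c
    v1 = np.asarray(p_after, dtype=float) - c
    r0 = float(np.hypot(*v0))
    r1 = float(np.hypot(*v1))
    if r0 == 0.0 or r1 == 0.0:
        raise ValueError("arc endpoints must be strictly off-center")
    a0 = math.atan2(v0[1], v0[0])
    a1 = math.atan2(v1[1], v1[0])
    da = math.remainder(a1 - a0, 2 * math.pi)  # minor arc, in (-pi, pi]
    if abs(abs(da) - math.pi) < ANTIPODAL_TOL_RAD:
        raise ValueError("antipodal arc endpoints")
    t = np.arange(1, k_missing + 1) / (k_missing + 1)
    ang = a0 + t * da
    rad = r0 + t * (r1 - r0)
    return np.column_stack([c[0] + rad * np.cos(ang), c[1] + rad * np.sin(ang)])


def repair_track(
    track: RawTrack,
    config: ArenaConfig,
    events: EventLog | None = None,
) -> RepairedTrack:
    """Fill every gap in a raw track and convert to mm / seconds.

    Returns a :class:`RepairedTrack` whose per-frame provenance records
    how each coordinate was obtained.  Edge-assigned frames contribute
    dwell time to the edge zone but, having no position, are excluded
    from track-length accumulation downstream.
    """
    n = track.n_frames
    x = track.x_px.copy()
    y = track.y_px.copy()
    prov = np.full(n, "observed", dtype="<U17")
    edge_assigned = np.zeros(n, dtype=bool)
    center = (config.center_x_px, config.center_y_px)

    for gap in find_gaps(track):
        cls = classify_gap(track, gap, config, events)
        sl = slice(gap.start, gap.stop + 1)
        if cls == "end_hold":
            x[sl] = x[gap.start - 1]
            y[sl] = y[gap.start - 1]
            prov[sl] = "held"
            continue
        p0 = (x[gap.start - 1], y[gap.start - 1])
        p1 = (x[gap.stop + 1], y[gap.stop + 1])
        if cls == "container_contact":
            x[sl] = p0[0]
            y[sl] = p0[1]
            prov[sl] = "container_contact"
        elif cls == "arc":
            try:
                pts = interpolate_arc(p0, p1, gap.k, center)
                prov[sl] = "arc"
            except ValueError:
                logger.warning(
                    "track %s: antipodal arc flanks at frames %d-%d, using straight line",
                    track.larva_id,
                    track.frames[gap.start],
                    track.frames[gap.stop],
                )
                pts = interpolate_linear(p0, p1, gap.k)
                prov[sl] = "linear"
            x[sl] = pts[:, 0]
            y[sl] = pts[:, 1]
        elif cls == "edge_assigned":
            x[sl] = np.nan
            y[sl] = np.nan
            prov[sl] = "edge_assigned"
            edge_assigned[sl] = True
        else:  # linear
            pts = interpolate_linear(p0, p1, gap.k)
            x[sl] = pts[:, 0]
            y[sl] = pts[:, 1]
            prov[sl] = "linear"

    x_mm = (x - config.center_x_px) * config.px_to_mm
    y_mm = (y - config.center_y_px) * config.px_to_mm
    r_mm = np.hypot(x_mm, y_mm)
    r_mm[edge_assigned] = config.edge_zone_midpoint_mm
    t_s = track.frames / config.frame_rate
    return RepairedTrack(
        larva_id=track.larva_id,
        frames=track.frames.copy(),
        t_s=t_s,
        x_mm=x_mm,
        y_mm=y_mm,
        r_mm=r_mm,
        provenance=prov,
        frame_rate=config.frame_rate,
    )
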