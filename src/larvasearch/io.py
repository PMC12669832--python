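"""Reading and writing tracking tables, event logs and repaired tracks.

Tracking tables are FIMtrack-style CSV: a header row, then one row per
(larva, frame) with pixel coordinates.  Frames at which detection failed
either appear with empty coordinate fields or are simply absent from the
file; both are represented internally as NaN within the dense frame
range of the track.  Column names vary between tracker versions, so the
reader takes a configurable ``column_map``.

Event logs are small per-experiment CSV or JSON files holding the four
manually recorded timestamps per larva (start, container placed, first
contact, container removed), in seconds from recording start.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RawTrack",
    "EventLog",
    "DEFAULT_COLUMN_MAP",
    "read_track_table",
    "stitch_fragments",
    "missing_fraction",
    "read_events",
    "write_events",
    "write_track_csv",
]

DEFAULT_COLUMN_MAP: dict[str, str] = {
    "frame": "frame",
    "x": "x",
    "y": "y",
    "larva_id": "larva_id",
    "edge_flag": "edge_flag",
}

EXCLUSION_REASONS = ("no-contact", "false-contact", "lid-approach")


@dataclass
class RawTrack:
    """Dense per-frame centroid track in pixel units.

    ``frames`` is a contiguous integer range from the first to the last
    observed frame; missing detections are NaN in ``x_px``/``y_px``.
    ``edge_flag`` marks frames visually verified to be at the arena wall
    (position unknown, zone membership known).
    """

    larva_id: str
    frames: np.ndarray
    x_px: np.ndarray
    y_px: np.ndarray
    edge_flag: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.int64)
        self.x_px = np.asarray(self.x_px, dtype=float)
        self.y_px = np.asarray(self.y_px, dtype=float)
        if self.edge_flag is None:
            self.edge_flag = np.zeros(self.frames.size, dtype=bool)
        else:
            self.edge_flag = np.asarray(self.edge_flag, dtype=bool)
        if not (self.frames.size == self.x_px.size == self.y_px.size == self.edge_flag.size):
            raise ValueError("frame/coordinate/flag arrays must have equal length")
        if self.frames.size == 0:
            raise ValueError("empty track")
        if np.any(np.diff(self.frames) != 1):
            raise ValueError("frames must be a contiguous increasing range")
        if not np.any(self.observed_mask):
            raise ValueError(f"track {self.larva_id!r} has no observed frame")

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.x_px) | np.isnan(self.y_px)

    @property
    def observed_mask(self) -> np.ndarray:
        return ~self.missing_mask

    @property
    def n_frames(self) -> int:
        return int(self.frames.size)

    @classmethod
    def from_observations(
        cls,
        larva_id: str,
        frame_idx: Sequence[int],
        x_px: Sequence[float],
        y_px: Sequence[float],
        edge_flag: Sequence[bool] | None = None,
    ) -> "RawTrack":
        """Densify sparse (frame, x, y) observations into a RawTrack.

        Frames absent between the first and last observation become
        missing (NaN).  Duplicate frame indices are an error.
        """
        frame_idx = np.asarray(frame_idx, dtype=np.int64)
        order = np.argsort(frame_idx, kind="stable")
        frame_idx = frame_idx[order]
        dup = frame_idx[np.where(np.diff(frame_idx) == 0)]
        if dup.size:
            raise ValueError(
                f"duplicate frame index for larva {larva_id!r}: {sorted(set(dup.tolist()))}"
            )
        x = np.asarray(x_px, dtype=float)[order]
        y = np.asarray(y_px, dtype=float)[order]
        ef = (
            np.zeros(frame_idx.size, dtype=bool)
            if edge_flag is None
            else np.asarray(edge_flag, dtype=bool)[order]
        )
        lo, hi = int(frame_idx[0]), int(frame_idx[-1])
        n = hi - lo + 1
        xd = np.full(n, np.nan)
        yd = np.full(n, np.nan)
        efd = np.zeros(n, dtype=bool)
        pos = frame_idx - lo
        xd[pos] = x
        yd[pos] = y
        efd[pos] = ef
        return cls(larva_id, np.arange(lo, hi + 1), xd, yd, efd)


@dataclass
class EventLog:
    """Manually recorded phase-boundary timestamps for one larva (seconds)."""

    larva_id: str
    t_start: float
    t_container_placed: float
    t_first_contact: float | None
    t_container_removed: float | None
    excluded: bool = False
    exclusion_reason: str | None = None

    def __post_init__(self) -> None:
        if self.excluded:
            if self.exclusion_reason is not None and self.exclusion_reason not in EXCLUSION_REASONS:
                raise ValueError(f"unknown exclusion reason {self.exclusion_reason!r}")
            return
        if self.t_first_contact is None or self.t_container_removed is None:
            raise ValueError(
                f"larva {self.larva_id!r}: non-excluded event log needs all four timestamps"
            )
        ok = (
            self.t_start <= self.t_container_placed
            and self.t_container_placed < self.t_first_contact
            and self.t_first_contact < self.t_container_removed
        )
        if not ok:
            raise ValueError(f"larva {self.larva_id!r}: event times out of order")

    @property
    def pre_search_duration_s(self) -> float | None:
        """Time from container placement to first contact (time-to-contact)."""
        if self.t_first_contact is None:
            return None
        return self.t_first_contact - self.t_container_placed


# ---------------------------------------------------------------------------
# tracking tables


def read_track_table(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
) -> dict[str, RawTrack]:
    """Read a tracking CSV into one :class:`RawTrack` per larva.

    Rows whose frame index or coordinates cannot be parsed raise an
    error listing the offending row numbers (1-based, excluding the
    header).  Empty coordinate fields mark a missing detection.
    """
    path = Path(path)
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for key in ("frame", "x", "y"):
        if cmap[key] not in df.columns:
            raise ValueError(f"column {cmap[key]!r} (for {key!r}) not found in {path}")

    # parse with Python's float() so coordinates round-trip bit-exactly
    # (pandas' numeric coercion is not guaranteed to)
    n_rows = len(df)
    frame = np.empty(n_rows, dtype=float)
    x = np.empty(n_rows, dtype=float)
    y = np.empty(n_rows, dtype=float)
    bad_rows: list[int] = []
    frame_col = df[cmap["frame"]].tolist()
    x_col = df[cmap["x"]].tolist()
    y_col = df[cmap["y"]].tolist()
    for i in range(n_rows):
        ok = True
        try:
            f = float(frame_col[i].strip())
            ok = f == int(f)
            frame[i] = f
        except ValueError:
            ok = False
        for col, dest in ((x_col, x), (y_col, y)):
            s = col[i].strip()
            if not s:
                dest[i] = np.nan
                continue
            try:
                dest[i] = float(s)
            except ValueError:
                ok = False
        if not ok:
            bad_rows.append(i + 1)
    if bad_rows:
        raise ValueError(f"unparseable rows in {path}: {bad_rows}")
    frame = pd.Series(frame, index=df.index)
    x = pd.Series(x, index=df.index)
    y = pd.Series(y, index=df.index)

    if cmap.get("larva_id") in df.columns:
        ids = df[cmap["larva_id"]].str.strip()
    else:
        ids = pd.Series([path.stem] * len(df))
    if cmap.get("edge_flag") in df.columns:
        ef = df[cmap["edge_flag"]].str.strip().str.lower().isin(("1", "true", "t", "yes"))
    else:
        ef = pd.Series(False, index=df.index)

    tracks: dict[str, RawTrack] = {}
    for larva_id, idx in ids.groupby(ids).groups.items():
        sub_frames = frame[idx].to_numpy(dtype=np.int64)
        tracks[str(larva_id)] = RawTrack.from_observations(
            str(larva_id),
            sub_frames,
            x[idx].to_numpy(),
            y[idx].to_numpy(),
            ef[idx].to_numpy(),
        )
    return tracks


def stitch_fragments(fragments: Sequence[RawTrack]) -> RawTrack:
    """Merge split track fragments of one larva into a single track.

    Fragments are ordered by first frame index; frames covered by no
    fragment become missing.  Overlapping frames must agree on the
    coordinates (trackers occasionally re-emit a boundary frame);
    conflicting overlaps are an error.
    """
    if not fragments:
        raise ValueError("no fragments")
    if len({f.larva_id for f in fragments}) != 1:
        raise ValueError("fragments belong to different larvae")
    frags = sorted(fragments, key=lambda f: int(f.frames[0]))
    lo = int(frags[0].frames[0])
    hi = max(int(f.frames[-1]) for f in frags)
    n = hi - lo + 1
    x = np.full(n, np.nan)
    y = np.full(n, np.nan)
    ef = np.zeros(n, dtype=bool)
    filled = np.zeros(n, dtype=bool)
    for f in frags:
        pos = f.frames - lo
        obs = f.observed_mask
        clash = filled[pos] & obs
        if np.any(clash):
            same = np.isclose(x[pos[clash]], f.x_px[clash], atol=1e-9) & np.isclose(
                y[pos[clash]], f.y_px[clash], atol=1e-9
            )
            if not np.all(same):
                conflicting = f.frames[clash][~same].tolist()
                raise ValueError(
                    f"overlapping fragments disagree at frames {conflicting}"
                )
        x[pos[obs]] = f.x_px[obs]
        y[pos[obs]] = f.y_px[obs]
        ef[pos] |= f.edge_flag
        filled[pos[obs]] = True
    return RawTrack(frags[0].larva_id, np.arange(lo, hi + 1), x, y, ef)


def missing_fraction(track: RawTrack) -> float:
    """Fraction of frames in [first, last] with failed detection (QC)."""
    return float(np.count_nonzero(track.missing_mask)) / track.n_frames


# ---------------------------------------------------------------------------
# event logs


def _event_from_record(rec: Mapping) -> EventLog:
    def _opt(key):
        v = rec.get(key)
        if v is None or (isinstance(v, str) and not v.strip()) or (
            isinstance(v, float) and np.isnan(v)
        ):
            return None
        return float(v)

    excl = rec.get("excluded", False)
    if isinstance(excl, str):
        excl = excl.strip().lower() in ("1", "true", "t", "yes")
    reason = rec.get("exclusion_reason") or None
    if isinstance(reason, str) and not reason.strip():
        reason = None
    return EventLog(
        larva_id=str(rec["larva_id"]),
        t_start=float(rec.get("t_start", 0.0) or 0.0),
        t_container_placed=float(rec["t_container_placed"]),
        t_first_contact=_opt("t_first_contact"),
        t_container_removed=_opt("t_container_removed"),
        excluded=bool(excl),
        exclusion_reason=reason,
    )


def read_events(path: str | Path) -> dict[str, EventLog]:
    """Read an events CSV or JSON file (one record per larva)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        records = json.loads(path.read_text())
        if isinstance(records, Mapping):
            records = list(records.values())
    else:
        records = pd.read_csv(path).to_dict(orient="records")
    events = [_event_from_record(r) for r in records]
    return {e.larva_id: e for e in events}


def write_events(events: Iterable[EventLog], path: str | Path) -> None:
    rows = []
    for e in events:
        rows.append(
            {
                "larva_id": e.larva_id,
                "t_start": e.t_start,
                "t_container_placed": e.t_container_placed,
                "t_first_contact": e.t_first_contact,
                "t_container_removed": e.t_container_removed,
                "excluded": e.excluded,
                "exclusion_reason": e.exclusion_reason or "",
            }
        )
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(rows, indent=2))
    else:
        pd.DataFrame(rows).to_csv(path, index=False)


def write_raw_track_csv(tracks: Iterable[RawTrack], path: str | Path) -> None:
    """Write raw tracks back to the FIMtrack-style CSV dialect.

    Missing frames are written with empty coordinate fields so that the
    read -> write -> read round trip is lossless.
    """
    rows = []
    for t in tracks:
        for i in range(t.n_frames):
            rows.append(
                {
                    "larva_id": t.larva_id,
                    "frame": int(t.frames[i]),
                    "x": "" if np.isnan(t.x_px[i]) else repr(float(t.x_px[i])),
                    "y": "" if np.isnan(t.y_px[i]) else repr(float(t.y_px[i])),
                    "edge_flag": int(bool(t.edge_flag[i])),
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def write_track_csv(repaired, path: str | Path) -> None:
    """Write a normalized per-larva track CSV (frame, t_s, x_mm, y_mm, r_mm, provenance)."""
    df = pd.DataFrame(
        {
            "frame": repaired.frames,
            "t_s": repaired.t_s,
            "x_mm": repaired.x_mm,
            "y_mm": repaired.y_mm,
            "r_mm": repaired.r_mm,
            "provenance": repaired.provenance,
        }
    )
    df.to_csv(path, index=False)
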