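"""Arena geometry and analysis constants.

The recording arena is a circular area (6 cm diameter) on an agarose
plate, imaged from below at 2 frames per second.  Tracking software
reports larval centroids in pixels; all analysis happens in millimetres
relative to the arena center.  The radial band structure used throughout
the package — seven 4 mm distance categories collapsed into four zones
(center / search / neutral / edge) — lives here, as does the geometry of
the center zone used for revisit counting.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

#: Names of the four concentric zones, innermost first.
ZONES = ("center", "search", "neutral", "edge")

#: Zone index (into ZONES) for each of the seven distance categories:
#: center = 0-4 + 4-8 mm, search = 8-12 + 12-16 mm,
#: neutral = 16-20 + 20-24 mm, edge = >24 mm.
CATEGORY_TO_ZONE = (0, 0, 1, 1, 2, 2, 3)

#: Number of distance categories.
N_CATEGORIES = 7


def center_zone_radius_cm(
    container_radius_cm: float = 0.35,
    median_larva_length_cm: float = 0.35,
    margin_cm: float = 0.10,
) -> float:
    """Reconstruct the center-zone radius from its physical components.

    The revisit boundary is the sum of the stimulus-container radius,
    the median larval body length and a safety margin absorbing larval
    size variance and imprecise container placement.  With the default
    components this gives 0.80 cm (the 8 mm boundary used everywhere).
    """
    return container_radius_cm + median_larva_length_cm + margin_cm


@dataclass(frozen=True)
class ArenaConfig:
    """Geometry and thresholds for one recording setup.

    Parameters
    ----------
    center_x_px, center_y_px
        Arena center in pixel coordinates of the tracking output.
    px_to_mm
        Scale factor, millimetres per pixel.
    frame_rate
        Recording rate in frames per second.
    arena_radius_mm
        Radius of the circular arena (lid) in mm.
    zone_edges_mm
        Inner boundaries of distance categories 1..6; category 0 starts
        at 0 mm and the last category is unbounded above.
    center_zone_radius_mm
        Revisit boundary (see :func:`center_zone_radius_cm`).
    edge_gap_threshold_mm
        Radial distance beyond which a detection gap flanked on both
        sides counts as wall-following and is filled along an arc.
    stop_displacement_mm
        Per-frame displacement below which the larva counts as stopped.
    stop_window_frames
        Number of consecutive moving frames that terminate a stop, and
        the maximal separation at which two stops merge into one.
    container_proximity_radius_mm
        Radius around the center within which a disappearance while the
        container is present is interpreted as container contact.
    """

    center_x_px: float = 512.0
    center_y_px: float = 512.0
    px_to_mm: float = 0.2673
    frame_rate: float = 2.0
    arena_radius_mm: float = 30.0
    zone_edges_mm: tuple[float, ...] = (4.0, 8.0, 12.0, 16.0, 20.0, 24.0)
    center_zone_radius_mm: float = 8.0
    edge_gap_threshold_mm: float = 21.3
    stop_displacement_mm: float = 0.05
    stop_window_frames: int = 5
    container_proximity_radius_mm: float = 8.0

    def __post_init__(self) -> None:
        if self.px_to_mm <= 0:
            raise ValueError("px_to_mm must be positive")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        edges = tuple(self.zone_edges_mm)
        if any(b <= a for a, b in zip(edges, edges[1:])):
            raise ValueError("zone_edges_mm must be strictly increasing")
        object.__setattr__(self, "zone_edges_mm", edges)

    @property
    def edge_zone_midpoint_mm(self) -> float:
        """Nominal radius assigned to frames known only to be at the wall."""
        return 0.5 * (self.zone_edges_mm[-1] + self.arena_radius_mm)

    # -- serialisation -------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["zone_edges_mm"] = list(d["zone_edges_mm"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ArenaConfig":
        d = dict(d)
        if "zone_edges_mm" in d:
            d["zone_edges_mm"] = tuple(d["zone_edges_mm"])
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "ArenaConfig":
        """Load from a YAML or JSON file (decided by suffix)."""
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() == ".json":
            return cls.from_dict(json.loads(text))
        return cls.from_dict(yaml.safe_load(text))

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix.lower() == ".json":
            path.write_text(json.dumps(self.to_dict(), indent=2))
        else:
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
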