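import numpy as np
import pytest

from larvasearch import ArenaConfig, RawTrack
from larvasearch.repair import RepairedTrack


@pytest.fixture
def arena() -> ArenaConfig:
    """Default recording geometry."""
    return ArenaConfig()


@pytest.fixture
def mm_arena() -> ArenaConfig:
    """Arena with center at the origin and 1 px = 1 mm, so pixel
    coordinates can be written directly in mm in geometry tests."""
    return ArenaConfig(center_x_px=0.0, center_y_px=0.0, px_to_mm=1.0)


def make_repaired(
    x_mm, y_mm=None, frame_rate: float = 2.0, larva_id: str = "larva"
) -> RepairedTrack:
    """Build a RepairedTrack directly from mm coordinates.

    If ``y_mm`` is omitted, ``x_mm`` is interpreted as a radius series
    and points are placed on the positive x axis.
    """
    x = np.asarray(x_mm, dtype=float)
    y = np.zeros_like(x) if y_mm is None else np.asarray(y_mm, dtype=float)
    frames = np.arange(x.size)
    return RepairedTrack(
        larva_id=larva_id,
        frames=frames,
        t_s=frames / frame_rate,
        x_mm=x,
        y_mm=y,
        r_mm=np.hypot(x, y),
        provenance=np.full(x.size, "observed", dtype="<U17"),
        frame_rate=frame_rate,
    )


@pytest.fixture
def track_factory():
    return make_repaired


def raw_from_sparse(frames, x, y, larva_id="larva", edge_flag=None) -> RawTrack:
    return RawTrack.from_observations(larva_id, frames, x, y, edge_flag)
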