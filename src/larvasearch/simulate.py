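"""Run-and-turn simulator for arena-scale larval tracks.

Larval crawling is modelled as an alternating sequence of runs and
reorientations: each frame the heading is nudged toward a preferred
radial band and perturbed by von Mises noise whose concentration sets
the heading persistence.  Two movement regimes reproduce the two
statistical signatures the analysis pipeline is built to detect:

* ``baseline_thigmotaxis`` — the preferred band sits just inside the
  arena wall, giving the rapid departure from the center and subsequent
  wall-hugging seen in unstimulated animals;
* ``local_search`` — after the (simulated) container removal the
  preferred band jumps to an inner ring (default 12 mm, the middle of
  the 8-16 mm search zone), producing center-orbiting;
* ``neutral`` — no radial bias, a plain persistent random walk.

On top of the walk the generator adds stop episodes (zero displacement
for a geometrically distributed number of frames), reflective collisions
with the arena wall, and detection dropout: missing-frame runs with
geometric lengths, optionally more frequent near the wall where real
trackers lose larvae against the lid.  Event logs (container placed /
first contact / removed) are drawn alongside so the full pipeline,
including phase segmentation, runs on simulated data alone.

Determinism: a master seed expands to per-larva child seeds through
``numpy.random.SeedSequence(master_seed, spawn_key=(larva_index,))``;
identical seed and configuration give bit-identical output.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, replace
from pathlib import Path

import numpy as np

from .config import ArenaConfig
from .io import EventLog, RawTrack, write_events, write_raw_track_csv

__all__ = ["SimConfig", "simulate_larva", "simulate_cohort", "write_cohort"]

MODES = ("baseline_thigmotaxis", "local_search", "neutral")

#: mm scale over which radial deviation saturates the steering bias
_RADIAL_GAIN_SCALE_MM = 5.0


@dataclass(frozen=True)
class SimConfig:
    """Generator parameters; defaults emulate the standard experiment.

    ``mode`` names the movement regime after container removal; before
    removal larvae always crawl in the thigmotactic baseline regime
    (except ``neutral``, which is unbiased throughout).  Times are in
    seconds, speeds in mm/s.
    """

    seed: int = 0
    n_larvae: int = 15
    mode: str = "local_search"
    frame_rate: float = 2.0
    arena_radius_mm: float = 30.0
    mean_speed_mm_s: float = 0.7
    speed_sd_mm_s: float = 0.15
    heading_persistence: float = 8.0  # von Mises concentration of turn noise
    wall_attraction_strength: float = 0.35
    wall_offset_mm: float = 2.5  # preferred distance inside the wall
    ring_attraction_radius_mm: float = 12.0
    ring_attraction_strength: float = 0.08
    stop_rate_per_min: float = 1.5
    stop_duration_frames_mean: float = 6.0
    excursion_rate_per_min: float = 3.0  # rate of leaving the biased state
    excursion_mean_s: float = 25.0  # mean duration of unbiased wandering
    dropout_rate: float = 0.02  # per-frame probability of starting a gap
    mean_gap_frames: float = 10.0
    edge_dropout_multiplier: float = 2.0  # dropout boost near the wall
    initial_placement: str = "center"  # "center" (placed by brush) or "stationary"
    baseline_s: float = 300.0
    pre_search_mean_s: float = 240.0
    pre_search_max_s: float = 900.0
    pre_search_min_s: float = 30.0
    investigation_s: float = 60.0
    search_s: float = 600.0

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.initial_placement not in ("center", "stationary"):
            raise ValueError(f"unknown initial_placement {self.initial_placement!r}")
        for name in (
            "stop_rate_per_min",
            "dropout_rate",
            "mean_speed_mm_s",
            "speed_sd_mm_s",
            "frame_rate",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def _child_rng(master_seed: int, larva_index: int) -> np.random.Generator:
    """Documented seeding rule: master seed + larva index -> child stream."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=master_seed, spawn_key=(larva_index,))
    )


def _draw_events(config: SimConfig, rng: np.random.Generator, larva_id: str) -> EventLog:
    pre = float(
        np.clip(
            rng.exponential(config.pre_search_mean_s),
            config.pre_search_min_s,
            config.pre_search_max_s,
        )
    )
    # quantize to the frame grid so phase boundaries align with frames
    dt = 1.0 / config.frame_rate
    pre = round(pre / dt) * dt
    t_placed = config.baseline_s
    t_contact = t_placed + pre
    t_removed = t_contact + config.investigation_s
    return EventLog(larva_id, 0.0, t_placed, t_contact, t_removed)


def _walk(
    config: SimConfig, rng: np.random.Generator, n_frames: int, switch_frame: int
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate positions (mm, arena-center origin) for one larva.

    With ``initial_placement="center"`` the larva starts at the origin,
    emulating placement by brush (the first minute then shows the
    characteristic dispersal toward the wall).  With ``"stationary"``
    the walk starts on the current regime's preferred band and a 120 s
    burn-in is discarded, so the recorded track samples the regime's
    steady state from frame 0 — the construction needed when the two
    analysis windows must be statistically exchangeable.
    """
    dt = 1.0 / config.frame_rate
    R = config.arena_radius_mm
    speed = max(0.1, float(rng.normal(config.mean_speed_mm_s, config.speed_sd_mm_s)))
    step = speed * dt
    chirality = 1.0 if rng.random() < 0.5 else -1.0
    heading = float(rng.uniform(0.0, 2.0 * math.pi))

    burn = int(round(120.0 * config.frame_rate)) if config.initial_placement == "stationary" else 0
    n_total = n_frames + burn

    # pre-drawn randomness; the per-frame loop is pure float arithmetic
    noise = rng.vonmises(0.0, config.heading_persistence, size=n_total)
    stop_u = rng.random(size=n_total)
    state_u = rng.random(size=n_total)
    p_stop = config.stop_rate_per_min * dt / 60.0
    # larvae alternate between target-biased crawling and unbiased
    # exploratory wandering; exit probabilities per frame
    p_leave_biased = config.excursion_rate_per_min * dt / 60.0
    p_leave_explore = dt / config.excursion_mean_s if config.excursion_mean_s > 0 else 1.0
    stop_lengths = (
        rng.geometric(1.0 / max(config.stop_duration_frames_mean, 1.0), size=n_total)
        if config.stop_rate_per_min > 0
        else np.zeros(n_total, dtype=np.int64)
    )

    x = np.empty(n_total)
    y = np.empty(n_total)
    if burn:
        if config.mode == "neutral":
            r0 = R * math.sqrt(rng.random())  # uniform over the arena area
        else:
            r0 = R - config.wall_offset_mm  # pre-switch regime hugs the wall
        a0 = rng.uniform(0.0, 2.0 * math.pi)
        px, py = r0 * math.cos(a0), r0 * math.sin(a0)
    else:
        px = py = 0.0  # larva is placed at the arena center
    x[0] = px
    y[0] = py
    stop_left = 0
    exploring = False
    two_pi = 2.0 * math.pi
    for i in range(1, n_total):
        if stop_left > 0:
            stop_left -= 1
            x[i] = px
            y[i] = py
            continue
        if stop_u[i] < p_stop:
            stop_left = int(stop_lengths[i])
            x[i] = px
            y[i] = py
            continue
        if exploring:
            if state_u[i] < p_leave_explore:
                exploring = False
        elif state_u[i] < p_leave_biased:
            exploring = True
        if config.mode == "neutral" or exploring:
            gain = 0.0
            desired = heading
        else:
            searching = (i - burn) >= switch_frame and config.mode == "local_search"
            if searching:
                target_r = config.ring_attraction_radius_mm
                gain = config.ring_attraction_strength
            else:
                target_r = R - config.wall_offset_mm
                gain = config.wall_attraction_strength
            r = math.hypot(px, py)
            if r < 1e-9:
                desired = heading
            else:
                ux, uy = px / r, py / r
                radial = (target_r - r) / _RADIAL_GAIN_SCALE_MM
                if radial > 2.0:
                    radial = 2.0
                elif radial < -2.0:
                    radial = -2.0
                vx = chirality * (-uy) + radial * ux
                vy = chirality * ux + radial * uy
                desired = math.atan2(vy, vx)
        turn = math.remainder(desired - heading, two_pi)
        heading = heading + gain * turn + noise[i]
        px += step * math.cos(heading)
        py += step * math.sin(heading)
        rr = math.hypot(px, py)
        if rr > R:
            # reflect across the tangent at the crossing point
            phi = math.atan2(py, px)
            scale = (2.0 * R - rr) / rr
            px *= scale
            py *= scale
            heading = 2.0 * phi + math.pi - heading
        x[i] = px
        y[i] = py
    return x[burn:], y[burn:]


def _apply_dropout(
    config: SimConfig, rng: np.random.Generator, x: np.ndarray, y: np.ndarray
) -> np.ndarray:
    """Missing-detection mask: geometric gap runs, denser near the wall."""
    n = x.size
    miss = np.zeros(n, dtype=bool)
    if config.dropout_rate <= 0:
        return miss
    r = np.hypot(x, y)
    near_wall = r > 0.8 * config.arena_radius_mm
    u = rng.random(size=n)
    gap_lengths = rng.geometric(1.0 / max(config.mean_gap_frames, 1.0), size=n)
    i = 1  # the first frame is always observed
    while i < n:
        p = config.dropout_rate * (config.edge_dropout_multiplier if near_wall[i] else 1.0)
        if u[i] < p:
            g = int(gap_lengths[i])
            miss[i : i + g] = True
            i += g + 1
        else:
            i += 1
    return miss


def simulate_larva(
    config: SimConfig,
    larva_index: int = 0,
    larva_id: str | None = None,
) -> tuple[RawTrack, EventLog]:
    """Simulate one larva: raw pixel-unit track plus its event log.

    The recording covers baseline + pre-search + investigation +
    ``search_s`` seconds; in ``local_search`` mode the movement regime
    switches at container removal.
    """
    rng = _child_rng(config.seed, larva_index)
    if larva_id is None:
        larva_id = f"larva_{larva_index:03d}"
    events = _draw_events(config, rng, larva_id)
    duration = events.t_container_removed + config.search_s
    n_frames = int(round(duration * config.frame_rate)) + 1
    switch_frame = int(round(events.t_container_removed * config.frame_rate))
    x_mm, y_mm = _walk(config, rng, n_frames, switch_frame)
    miss = _apply_dropout(config, rng, x_mm, y_mm)

    arena = ArenaConfig(arena_radius_mm=config.arena_radius_mm, frame_rate=config.frame_rate)
    x_px = arena.center_x_px + x_mm / arena.px_to_mm
    y_px = arena.center_y_px + y_mm / arena.px_to_mm
    x_px[miss] = np.nan
    y_px[miss] = np.nan
    track = RawTrack(larva_id, np.arange(n_frames), x_px, y_px)
    return track, events


def simulate_cohort(
    config: SimConfig, n: int | None = None
) -> list[tuple[RawTrack, EventLog]]:
    """Simulate ``n`` independent larvae (default ``config.n_larvae``).

    Child seeds derive reproducibly from the master seed, so the cohort
    is bit-identical across runs and insensitive to evaluation order.
    """
    if n is None:
        n = config.n_larvae
    if n < 1:
        raise ValueError("n must be >= 1")
    return [simulate_larva(config, i) for i in range(n)]


def write_cohort(
    cohort: list[tuple[RawTrack, EventLog]],
    outdir: str | Path,
    config: SimConfig | None = None,
) -> dict:
    """Write a simulated cohort in the pipeline's input formats.

    One tracking CSV per larva, a shared events CSV, the arena config,
    and (if given) an echo of the generator configuration.  Returns a
    manifest dictionary pointing at the files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    arena = ArenaConfig(
        arena_radius_mm=config.arena_radius_mm if config else 30.0,
        frame_rate=config.frame_rate if config else 2.0,
    )
    entries = []
    for track, _ in cohort:
        track_path = outdir / f"{track.larva_id}_track.csv"
        write_raw_track_csv([track], track_path)
        entries.append({"track": track_path.name, "larva_id": track.larva_id})
    events_path = outdir / "events.csv"
    write_events([ev for _, ev in cohort], events_path)
    arena.to_file(outdir / "arena.yaml")
    manifest = {
        "entries": entries,
        "events": events_path.name,
        "arena": "arena.yaml",
    }
    if config is not None:
        (outdir / "sim_config.json").write_text(json.dumps(asdict(config), indent=2))
        manifest["sim_config"] = "sim_config.json"
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
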