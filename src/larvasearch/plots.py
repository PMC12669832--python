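"""Standard figure set for arena residency analyses.

Grayscale position rasters (one row per larva, gray level = zone),
per-category pie charts of dwell time and path length, box plots with
significance stars, and 10-frame-averaged speed traces.  Color ramps
run dark to light from the arena center outward.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .config import N_CATEGORIES, ZONES, ArenaConfig
from .metrics import SpeedSeries, zone_of
from .phases import ExperimentTimeline
from .repair import RepairedTrack
from .stats import significance_stars

__all__ = [
    "grayscale_position_plot",
    "zone_pie_and_box_figures",
    "pie_figure",
    "box_plot_with_stars",
    "speed_trace_figure",
]

#: gray values for center / search / neutral / edge rows, dark to light
ZONE_GRAYS = (0.15, 0.45, 0.7, 0.9)

#: dark red -> beige for time pies; dark green -> light green for length
TIME_PIE_CMAP = "OrRd_r"
LENGTH_PIE_CMAP = "Greens_r"


def grayscale_position_plot(
    tracks: list[RepairedTrack],
    timelines: list[ExperimentTimeline],
    config: ArenaConfig,
) -> plt.Figure:
    """One gray row per larva over time, sorted by time-to-contact.

    The gray level of each frame encodes the larva's zone (dark =
    center zone, light = edge zone); larvae that found the container
    fastest are drawn at the top, and phase boundaries are marked.
    """
    if not tracks:
        raise ValueError("no tracks to plot")
    pre_durations = [tl.pre_search[1] - tl.pre_search[0] for tl in timelines]
    order = np.argsort(pre_durations, kind="stable")
    n_cols = max(t.n_frames for t in tracks)
    img = np.ones((len(tracks), n_cols))
    for row, i in enumerate(order):
        tr = tracks[i]
        z = zone_of(tr.r_mm, config.zone_edges_mm)
        img[row, : tr.n_frames] = np.asarray(ZONE_GRAYS)[z]
    fig, ax = plt.subplots(figsize=(10, 0.3 * len(tracks) + 1.5))
    ax.imshow(img, cmap="gray", vmin=0, vmax=1, aspect="auto", interpolation="nearest")
    top = tracks[order[0]]
    for t_evt in (timelines[order[0]].baseline[1],):
        ax.axvline(t_evt * config.frame_rate, color="tab:blue", lw=0.8)
    ax.set_xlabel("frame")
    ax.set_ylabel("larva (fastest contact on top)")
    ax.set_yticks(range(len(tracks)))
    ax.set_yticklabels([tracks[i].larva_id for i in order], fontsize=6)
    fig.tight_layout()
    return fig


def pie_figure(fractions: np.ndarray, title: str, cmap: str = TIME_PIE_CMAP) -> plt.Figure:
    """Pie of per-category proportions, counterclockwise from the center category."""
    fractions = np.asarray(fractions, dtype=float)
    total = fractions.sum()
    if total <= 0:
        raise ValueError("nothing to plot")
    fractions = fractions / total
    colors = plt.get_cmap(cmap)(np.linspace(0.15, 0.85, fractions.size))
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.pie(
        fractions,
        colors=colors,
        counterclock=True,
        startangle=90,
        labels=[f"cat{i}" for i in range(fractions.size)],
        normalize=True,
    )
    ax.set_title(title)
    return fig


def box_plot_with_stars(
    samples: list[np.ndarray],
    labels: list[str],
    p_value: float | None = None,
    ylabel: str = "",
) -> plt.Figure:
    """Box plot with median line, quartile box and min/max whiskers.

    Whiskers span the full data range (no outlier clipping), and an
    optional pairwise p-value is rendered as significance stars.
    """
    fig, ax = plt.subplots(figsize=(1.2 * len(samples) + 1.5, 4))
    ax.boxplot(samples, tick_labels=labels, whis=(0, 100), showfliers=False)
    ax.set_ylabel(ylabel)
    if p_value is not None and len(samples) == 2:
        y = max(np.max(s) for s in samples)
        span = y - min(np.min(s) for s in samples) or 1.0
        ax.plot([1, 2], [y + 0.05 * span] * 2, color="k", lw=1)
        ax.text(1.5, y + 0.07 * span, significance_stars(p_value), ha="center")
    fig.tight_layout()
    return fig


def speed_trace_figure(series: list[SpeedSeries], title: str = "speed") -> plt.Figure:
    """Ten-frame-averaged individual speed traces plus the cohort mean."""
    fig, ax = plt.subplots(figsize=(8, 3))
    common = None
    for s in series:
        if s.smoothed_mm_s.size:
            ax.plot(s.t_smooth_s, s.smoothed_mm_s, color="0.7", lw=0.6)
    lengths = [s.smoothed_mm_s.size for s in series if s.smoothed_mm_s.size]
    if lengths:
        n = min(lengths)
        stack = np.vstack([s.smoothed_mm_s[:n] for s in series if s.smoothed_mm_s.size])
        t = next(s.t_smooth_s[:n] for s in series if s.smoothed_mm_s.size)
        ax.plot(t, stack.mean(axis=0), color="tab:blue", lw=1.5)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("speed (mm/s)")
    ax.set_title(title)
    fig.tight_layout()
    return fig


def zone_pie_and_box_figures(metrics: pd.DataFrame) -> list[tuple[plt.Figure, str]]:
    """Standard per-cohort figure set from the tidy metrics table.

    Per phase: a dwell-time pie and a path-length pie over the seven
    distance categories; plus baseline-vs-search box plots of the
    search score and the median distance to center.
    """
    if metrics.empty:
        raise ValueError("empty metrics table")
    figs: list[tuple[plt.Figure, str]] = []
    time_cols = [f"time_cat{i}_s" for i in range(N_CATEGORIES)]
    len_cols = [f"length_cat{i}_mm" for i in range(N_CATEGORIES)]
    for phase in metrics["phase"].unique():
        sub = metrics[metrics.phase == phase]
        t = sub[time_cols].sum(axis=0).to_numpy()
        figs.append((pie_figure(t, f"time per category ({phase})", TIME_PIE_CMAP), f"time_pie_{phase}"))
        ln = sub[len_cols].sum(axis=0).to_numpy()
        if ln.sum() > 0:
            figs.append(
                (pie_figure(ln, f"length per category ({phase})", LENGTH_PIE_CMAP), f"length_pie_{phase}")
            )
    base = metrics[metrics.phase == "baseline"]
    search = metrics[metrics.phase == "search"]
    if len(base) and len(search):
        from .stats import wilcoxon_paired

        common = base.set_index("larva_id").index.intersection(
            search.set_index("larva_id").index
        )
        for metric, label in (("search_score", "search score"), ("median_r_mm", "distance to center (mm)")):
            a = base.set_index("larva_id").loc[common, metric].to_numpy()
            b = search.set_index("larva_id").loc[common, metric].to_numpy()
            p = wilcoxon_paired(a, b).p_value if len(common) >= 5 else None
            figs.append(
                (
                    box_plot_with_stars([a, b], ["baseline", "search"], p, label),
                    f"box_{metric}",
                )
            )
    return figs
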