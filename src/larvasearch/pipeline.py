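"""Batch orchestration: tracks + events -> metrics, statistics, reports.

Two entry points:

* :func:`analyze_cohort` works on in-memory (RawTrack, EventLog) pairs
  — the route the simulator and the test suite use;
* :func:`run_pipeline` reads a manifest of files, runs the same
  analysis per condition, writes tidy CSV/JSON outputs (and figures on
  request) and echoes the manifest for provenance.

Cohort statistics follow a fixed scheme: every scalar metric gets a
paired baseline-vs-search Wilcoxon signed-rank test; search scores are
additionally tested against zero per phase; across conditions the
search-phase score is compared with a Mann-Whitney U test (two
conditions) or a Kruskal-Wallis test with post hoc pairwise
comparisons (three or more).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .config import ArenaConfig
from .datasets import format_min_s
from .io import EventLog, RawTrack, missing_fraction, read_events, read_track_table
from .metrics import PhaseMetrics, compute_phase_metrics
from .phases import segment_phases
from .repair import RepairedTrack, repair_track
from .stats import (
    TestResult,
    kruskal_wallis,
    mann_whitney_u,
    posthoc_pairwise,
    wilcoxon_one_sample,
    wilcoxon_paired,
)

logger = logging.getLogger(__name__)

__all__ = [
    "BatchManifest",
    "ManifestEntry",
    "CohortResult",
    "analyze_cohort",
    "compare_conditions",
    "run_pipeline",
    "summarize_time_to_contact",
]

#: scalar metrics compared baseline vs search for every cohort
PAIRED_METRICS = (
    "search_score",
    "median_r_mm",
    "total_length_mm",
    "median_speed_mm_s",
    "time_in_center_zone_s",
    "n_revisits",
    "n_stops",
)

#: larvae losing more than this fraction of frames fail QC
DEFAULT_MAX_MISSING_FRACTION = 0.60


@dataclass(frozen=True)
class ManifestEntry:
    track_path: str
    events_path: str
    condition: str = "default"


@dataclass
class BatchManifest:
    """File-level description of one analysis batch."""

    entries: list[ManifestEntry]
    arena: ArenaConfig
    outdir: str
    max_missing_fraction: float = DEFAULT_MAX_MISSING_FRACTION
    make_figures: bool = False

    @classmethod
    def from_file(cls, path: str | Path) -> "BatchManifest":
        path = Path(path)
        text = path.read_text()
        d = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
        base = path.parent

        def _resolve(p: str) -> str:
            q = Path(p)
            return str(q if q.is_absolute() else base / q)

        entries = [
            ManifestEntry(
                _resolve(e["track_path"]),
                _resolve(e["events_path"]),
                e.get("condition", "default"),
            )
            for e in d["entries"]
        ]
        arena = (
            ArenaConfig.from_file(_resolve(d["arena"]))
            if isinstance(d.get("arena"), str)
            else ArenaConfig.from_dict(d.get("arena", {}))
        )
        return cls(
            entries=entries,
            arena=arena,
            outdir=_resolve(d.get("outdir", "results")),
            max_missing_fraction=float(
                d.get("max_missing_fraction", DEFAULT_MAX_MISSING_FRACTION)
            ),
            make_figures=bool(d.get("make_figures", False)),
        )

    def to_dict(self) -> dict:
        return {
            "entries": [
                {
                    "track_path": e.track_path,
                    "events_path": e.events_path,
                    "condition": e.condition,
                }
                for e in self.entries
            ],
            "arena": self.arena.to_dict(),
            "outdir": self.outdir,
            "max_missing_fraction": self.max_missing_fraction,
            "make_figures": self.make_figures,
        }


@dataclass
class CohortResult:
    """Everything computed for one cohort (one condition)."""

    condition: str
    repaired: list[RepairedTrack]
    timelines: list
    per_phase: list[PhaseMetrics]
    metrics: pd.DataFrame  # tidy: one row per larva per phase
    minute_bins: pd.DataFrame
    stats: pd.DataFrame
    qc: list[dict]
    excluded: list[dict]


def _phase_frame(per_phase: list[PhaseMetrics]) -> pd.DataFrame:
    return pd.DataFrame([pm.scalar_row() for pm in per_phase])


def _cohort_stats(metrics: pd.DataFrame) -> pd.DataFrame:
    rows = []
    base = metrics[metrics.phase == "baseline"].set_index("larva_id")
    search = metrics[metrics.phase == "search"].set_index("larva_id")
    common = base.index.intersection(search.index)
    for metric in PAIRED_METRICS:
        if len(common) < 5:
            logger.warning("fewer than 5 paired larvae; skipping paired tests")
            break
        res = wilcoxon_paired(
            base.loc[common, metric].to_numpy(), search.loc[common, metric].to_numpy()
        )
        rows.append({"comparison": f"{metric}: baseline vs search", **res.row()})
    for phase_name, df in (("baseline", base), ("search", search)):
        if len(df) >= 5:
            res = wilcoxon_one_sample(df["search_score"].to_numpy())
            rows.append({"comparison": f"search_score ({phase_name}) vs 0", **res.row()})
    return pd.DataFrame(rows)


def analyze_cohort(
    pairs: list[tuple[RawTrack, EventLog]],
    config: ArenaConfig,
    condition: str = "default",
    max_missing_fraction: float = DEFAULT_MAX_MISSING_FRACTION,
) -> CohortResult:
    """Repair, segment and score every larva of one cohort.

    Larvae whose event log is marked excluded, or that fail the
    missing-fraction QC threshold, are dropped with a logged reason.
    """
    if not pairs:
        raise ValueError("empty cohort")
    repaired, timelines, per_phase, qc, excluded = [], [], [], [], []
    minute_rows = []
    for track, events in pairs:
        frac = missing_fraction(track)
        if events.excluded:
            excluded.append(
                {"larva_id": track.larva_id, "reason": events.exclusion_reason or "excluded"}
            )
            continue
        if frac > max_missing_fraction:
            excluded.append(
                {"larva_id": track.larva_id, "reason": f"missing_fraction={frac:.3f}"}
            )
            continue
        rep = repair_track(track, config, events)
        timeline = segment_phases(events, recording_end_s=float(rep.t_s[-1] + 1e-9))
        repaired.append(rep)
        timelines.append(timeline)
        qc.append(
            {
                "larva_id": track.larva_id,
                "missing_fraction": frac,
                "n_frames": track.n_frames,
                "truncated_search": timeline.truncated,
            }
        )
        for phase_name, window in timeline.phases.items():
            pm = compute_phase_metrics(rep, window, phase_name, config)
            per_phase.append(pm)
            for b in pm.r_per_minute_mm:
                minute_rows.append({"larva_id": rep.larva_id, "phase": phase_name, **b})
    if not repaired:
        raise ValueError(f"cohort {condition!r}: every larva was excluded")
    metrics = _phase_frame(per_phase)
    metrics.insert(0, "condition", condition)
    stats = _cohort_stats(metrics)
    if not stats.empty:
        stats.insert(0, "condition", condition)
    return CohortResult(
        condition=condition,
        repaired=repaired,
        timelines=timelines,
        per_phase=per_phase,
        metrics=metrics,
        minute_bins=pd.DataFrame(minute_rows),
        stats=stats,
        qc=qc,
        excluded=excluded,
    )


def compare_conditions(results: list[CohortResult], metric: str = "search_score") -> pd.DataFrame:
    """Cross-condition comparison of the search-phase value of a metric.

    Two conditions: Mann-Whitney U.  Three or more: Kruskal-Wallis,
    with post hoc pairwise comparisons only if the global test is
    significant.
    """
    groups, labels = [], []
    for res in results:
        vals = res.metrics.loc[res.metrics.phase == "search", metric].to_numpy()
        groups.append(vals)
        labels.append(res.condition)
    rows = []
    if len(groups) < 2:
        return pd.DataFrame(rows)
    if len(groups) == 2:
        r = mann_whitney_u(groups[0], groups[1])
        rows.append({"comparison": f"{metric}: {labels[0]} vs {labels[1]}", **r.row()})
    else:
        r = kruskal_wallis(groups)
        rows.append({"comparison": f"{metric}: global ({', '.join(labels)})", **r.row()})
        for ph in posthoc_pairwise(groups, labels):
            rows.append(
                {
                    "comparison": f"{metric}: {ph['comparison']}",
                    "method": ph["method"],
                    "statistic": ph["statistic"],
                    "p": ph["p_adj"],
                    "n": "",
                    "stars": ph["stars"],
                    "exact": "",
                    "note": f"p_raw={ph['p_raw']:.4g}",
                }
            )
    return pd.DataFrame(rows)


def summarize_time_to_contact(events_by_condition: dict[str, list]) -> pd.DataFrame:
    """Per-condition table of times to find the container.

    Accepts either EventLog lists (pre-search durations are extracted)
    or plain lists of seconds.  Rows are individual larvae formatted
    min:s; a final row holds the arithmetic mean rounded to the nearest
    second.
    """
    cols = {}
    for cond, items in events_by_condition.items():
        secs = []
        for it in items:
            if isinstance(it, EventLog):
                if it.excluded or it.pre_search_duration_s is None:
                    continue
                secs.append(it.pre_search_duration_s)
            else:
                secs.append(float(it))
        if not secs:
            raise ValueError(f"condition {cond!r} has no usable times")
        cols[cond] = secs
    n_max = max(len(v) for v in cols.values())
    table = {}
    for cond, secs in cols.items():
        col = [format_min_s(s) for s in secs] + [""] * (n_max - len(secs))
        col.append(format_min_s(float(np.mean(secs))))
        table[cond] = col
    index = [str(i + 1) for i in range(n_max)] + ["mean"]
    return pd.DataFrame(table, index=index)


def run_pipeline(manifest: BatchManifest) -> dict[str, CohortResult]:
    """Run the full batch analysis described by a manifest.

    Writes per-larva metrics, minute bins, statistics, QC and a
    manifest echo under ``manifest.outdir``; figures when
    ``make_figures`` is set.  Returns the per-condition results.
    """
    if not manifest.entries:
        raise ValueError("empty manifest")
    outdir = Path(manifest.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    by_condition: dict[str, list[tuple[RawTrack, EventLog]]] = {}
    for entry in manifest.entries:
        tracks = read_track_table(entry.track_path)
        events = read_events(entry.events_path)
        for larva_id, track in tracks.items():
            if larva_id not in events:
                raise ValueError(f"no event log for larva {larva_id!r} in {entry.events_path}")
            by_condition.setdefault(entry.condition, []).append((track, events[larva_id]))

    results = {}
    for condition, pairs in by_condition.items():
        results[condition] = analyze_cohort(
            pairs, manifest.arena, condition, manifest.max_missing_fraction
        )

    all_metrics = pd.concat([r.metrics for r in results.values()], ignore_index=True)
    all_minutes = pd.concat([r.minute_bins for r in results.values()], ignore_index=True)
    all_stats = pd.concat(
        [r.stats for r in results.values() if not r.stats.empty], ignore_index=True
    )
    cross = compare_conditions(list(results.values()))
    if not cross.empty:
        all_stats = pd.concat([all_stats, cross], ignore_index=True)

    all_metrics.to_csv(outdir / "metrics.csv", index=False)
    all_minutes.to_csv(outdir / "minute_bins.csv", index=False)
    all_stats.to_csv(outdir / "stats.csv", index=False)
    summary = {
        "conditions": {
            c: {
                "n_analyzed": len(r.repaired),
                "n_excluded": len(r.excluded),
                "excluded": r.excluded,
                "qc": r.qc,
                "contact_rate": len(r.repaired) / (len(r.repaired) + len(r.excluded))
                if (len(r.repaired) + len(r.excluded))
                else None,
            }
            for c, r in results.items()
        }
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2))
    (outdir / "manifest_echo.json").write_text(json.dumps(manifest.to_dict(), indent=2))

    if manifest.make_figures:
        from . import plots

        for condition, res in results.items():
            fig = plots.grayscale_position_plot(res.repaired, res.timelines, manifest.arena)
            fig.savefig(outdir / f"{condition}_positions.png", dpi=150)
            for f, name in plots.zone_pie_and_box_figures(res.metrics):
                f.savefig(outdir / f"{condition}_{name}.png", dpi=150)
    return results
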