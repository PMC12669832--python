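"""Segmentation of an experiment into its four phases.

An experiment runs: a 5 min acclimation/exploration window (baseline),
then the stimulus container is placed (pre-search, up to 15 min until
the larva first touches it), a 1 min investigation window with the
container present, and after its removal an observation window of which
the first 5 min are analyzed (search).  Control recordings without a
container are segmented with artificial event times using the same
machinery.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .io import EventLog

logger = logging.getLogger(__name__)

__all__ = ["ExperimentTimeline", "segment_phases", "PHASES"]

PHASES = ("baseline", "pre_search", "investigation", "search")

#: Length of the analyzed part of the search phase, seconds.
SEARCH_ANALYSIS_WINDOW_S = 300.0


@dataclass(frozen=True)
class ExperimentTimeline:
    """Half-open [t0, t1) windows, seconds from recording start."""

    baseline: tuple[float, float]
    pre_search: tuple[float, float]
    investigation: tuple[float, float]
    search_analyzed: tuple[float, float]
    truncated: bool = False

    def window(self, phase: str) -> tuple[float, float]:
        if phase == "search":
            phase = "search_analyzed"
        return getattr(self, phase)

    @property
    def phases(self) -> dict[str, tuple[float, float]]:
        return {
            "baseline": self.baseline,
            "pre_search": self.pre_search,
            "investigation": self.investigation,
            "search": self.search_analyzed,
        }


def segment_phases(
    events: EventLog,
    recording_end_s: float | None = None,
    search_window_s: float = SEARCH_ANALYSIS_WINDOW_S,
) -> ExperimentTimeline:
    """Derive the four phase windows from an event log.

    The analyzed search window is ``search_window_s`` (default 300 s)
    from container removal; if the recording ends earlier the window is
    truncated and a warning logged.
    """
    if events.excluded:
        raise ValueError(f"larva {events.larva_id!r} is excluded ({events.exclusion_reason})")
    for name in ("t_first_contact", "t_container_removed"):
        if getattr(events, name) is None:
            raise ValueError(f"larva {events.larva_id!r}: missing event {name}")
    t_search_end = events.t_container_removed + search_window_s
    truncated = False
    if recording_end_s is not None and recording_end_s < t_search_end:
        logger.warning(
            "larva %s: recording ends at %.1f s, search window truncated to %.1f s",
            events.larva_id,
            recording_end_s,
            recording_end_s - events.t_container_removed,
        )
        t_search_end = recording_end_s
        truncated = True
    return ExperimentTimeline(
        baseline=(events.t_start, events.t_container_placed),
        pre_search=(events.t_container_placed, events.t_first_contact),
        investigation=(events.t_first_contact, events.t_container_removed),
        search_analyzed=(events.t_container_removed, t_search_end),
        truncated=truncated,
    )
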