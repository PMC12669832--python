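"""Bundled example data: measured times to find a yeast container.

Per-larva times (min:s from container placement to first physical
contact) measured at four baker's-yeast concentrations.  The columns
have unequal lengths because different numbers of larvae reached the
container at each concentration.  Used by the reporting helpers as a
worked example of per-condition time-to-contact tables.
"""

from __future__ import annotations

__all__ = ["yeast_time_to_contact", "parse_min_s", "format_min_s"]

_YEAST_TIMES_MIN_S: dict[str, list[str]] = {
    "25%": [
        "02:52", "09:29", "01:50", "00:17", "06:05", "03:09", "01:08", "02:59",
        "02:56", "05:15", "00:41", "09:22", "00:29", "05:35", "02:08", "02:07",
        "01:35",
    ],
    "50%": [
        "04:08", "00:23", "14:54", "14:59", "12:29", "01:51", "02:24", "03:30",
        "08:15", "01:40", "09:09", "03:20", "13:45", "10:03",
    ],
    "75%": [
        "00:31", "01:39", "03:44", "06:56", "04:06", "03:17", "02:47", "06:02",
        "03:05", "05:42", "12:01", "02:26", "00:32", "11:02", "05:41", "02:32",
        "00:26", "01:27",
    ],
    "100%": [
        "09:30", "04:57", "04:11", "04:57", "00:59", "01:11", "12:28", "00:45",
        "01:14", "00:45", "07:14", "11:21", "09:01", "03:17", "00:35", "01:19",
        "01:06", "01:13",
    ],
}


def parse_min_s(text: str) -> float:
    """'mm:ss' -> seconds."""
    minutes, seconds = text.split(":")
    return 60.0 * int(minutes) + float(seconds)


def format_min_s(seconds: float) -> str:
    """Seconds -> 'm:ss', rounded to the nearest second."""
    total = int(round(seconds))
    return f"{total // 60}:{total % 60:02d}"


def yeast_time_to_contact() -> dict[str, list[float]]:
    """Times to find the yeast container, in seconds, per concentration."""
    return {k: [parse_min_s(t) for t in v] for k, v in _YEAST_TIMES_MIN_S.items()}
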