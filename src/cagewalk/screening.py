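"""Detection and exclusion of corrupted event-log segments.

Long hardware outages (antenna or controller faults) leave either explicit
fault flags or cage-wide silent gaps in the event stream. Both are detected
here and turned into :class:`ExclusionInterval` spans that downstream
binning treats as missing. By default exclusions are snapped outward to
whole 12-h analysis bins, so affected bins are dropped entirely rather
than renormalized — partially observed bins would bias percentage metrics.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Sequence

import csv

from cagewalk.events_io import EventLog, VisitEvent

if TYPE_CHECKING:  # pragma: no cover
    from cagewalk.metrics import BinGrid

__all__ = [
    "ExclusionInterval",
    "merge_intervals",
    "detect_corruption",
    "apply_exclusions",
    "read_exclusions",
    "write_exclusions",
]

DEFAULT_GAP_THRESHOLD_S = 3600.0


@dataclass(frozen=True, order=True)
class ExclusionInterval:
    """A half-open time span ``[start_s, end_s)`` removed from analysis."""

    start_s: float
    end_s: float
    reason: str = "manual"

    def __post_init__(self) -> None:
        if not self.end_s > self.start_s:
            raise ValueError(
                f"ExclusionInterval requires end_s > start_s, got [{self.start_s}, {self.end_s})"
            )

    def contains(self, t: float) -> bool:
        return self.start_s <= t < self.end_s


def merge_intervals(intervals: Iterable[ExclusionInterval]) -> list[ExclusionInterval]:
    """Sort intervals and merge overlapping or touching ones.

    Reasons of merged spans are joined with ``+`` (duplicates collapsed).
    """
    ivs = sorted(intervals)
    out: list[ExclusionInterval] = []
    for iv in ivs:
        if out and iv.start_s <= out[-1].end_s:
            prev = out[-1]
            reasons = list(dict.fromkeys(prev.reason.split("+") + iv.reason.split("+")))
            out[-1] = ExclusionInterval(
                prev.start_s, max(prev.end_s, iv.end_s), "+".join(reasons)
            )
        else:
            out.append(iv)
    return out


def _event_times(log: EventLog) -> list[float]:
    times: list[float] = []
    for v in log.visits:
        times.append(v.start_s)
        times.append(v.end_s)
    times.sort()
    return times


def detect_corruption(
    log: EventLog,
    gap_threshold_s: float = DEFAULT_GAP_THRESHOLD_S,
    snap_to_bins: "BinGrid | None" = None,
) -> list[ExclusionInterval]:
    """Detect corrupted segments from hardware flags and silent gaps.

    Two detectors run:

    * **flagged** — hardware flags, sorted by time, are paired consecutively
      (1st with 2nd, 3rd with 4th, ...) into bracketed fault spans; a
      trailing unpaired flag extends to the last event in the log.
    * **silent-gap** — cage-wide spans of at least ``gap_threshold_s``
      between consecutive events of *any* animal; a healthy group-housed
      cage is never silent for long.

    If ``snap_to_bins`` is given, each interval is expanded outward to the
    grid's bin boundaries (so whole analysis bins are dropped). Returned
    intervals are merged: pairwise disjoint and sorted.
    """
    if gap_threshold_s <= 0:
        raise ValueError("gap_threshold_s must be positive")
    found: list[ExclusionInterval] = []

    flags = sorted(log.flags, key=lambda f: f.time_s)
    span_end = log.span()[1]
    for i in range(0, len(flags) - 1, 2):
        a, b = flags[i], flags[i + 1]
        if b.time_s > a.time_s:
            found.append(ExclusionInterval(a.time_s, b.time_s, "flagged"))
    if len(flags) % 2 == 1 and span_end > flags[-1].time_s:
        found.append(ExclusionInterval(flags[-1].time_s, span_end, "flagged"))

    times = _event_times(log)
    for t1, t2 in zip(times, times[1:]):
        if t2 - t1 >= gap_threshold_s:
            found.append(ExclusionInterval(t1, t2, "silent-gap"))

    if snap_to_bins is not None:
        found = [
            ExclusionInterval(
                snap_to_bins.floor(iv.start_s), snap_to_bins.ceil(iv.end_s), iv.reason
            )
            for iv in found
        ]
    return merge_intervals(found)


def apply_exclusions(
    log: EventLog, intervals: Sequence[ExclusionInterval]
) -> tuple[EventLog, int]:
    """Drop every visit starting inside an excluded interval.

    A visit is *inside* an interval iff its start time is (half-open
    convention). Returns the filtered log and the number of dropped visits;
    kept + dropped always equals the original visit count. Intervals must
    be disjoint and sorted (as produced by :func:`merge_intervals`).
    """
    for a, b in zip(intervals, intervals[1:]):
        if b.start_s < a.end_s:
            raise ValueError(
                f"overlapping exclusion intervals: [{a.start_s},{a.end_s}) and "
                f"[{b.start_s},{b.end_s})"
            )
    if not intervals:
        return log, 0
    kept: list[VisitEvent] = []
    dropped = 0
    for v in log.visits:
        if any(iv.contains(v.start_s) for iv in intervals):
            dropped += 1
        else:
            kept.append(v)
    out = EventLog(log.animals, tuple(kept), log.flags, log.t0_clock)
    return out, dropped


def write_exclusions(intervals: Sequence[ExclusionInterval], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["start_s", "end_s", "reason"])
        for iv in intervals:
            w.writerow([repr(iv.start_s), repr(iv.end_s), iv.reason])


def read_exclusions(path: str | Path) -> list[ExclusionInterval]:
    out = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        for row in reader:
            out.append(
                ExclusionInterval(float(row["start_s"]), float(row["end_s"]), row["reason"])
            )
    return merge_intervals(out)
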