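"""Event data model and CSV event-log dialect.

The instrument's native archive format is proprietary and undocumented;
this module defines a plain, documented CSV interchange dialect instead
(see :func:`read_event_log`). A log is a directory of UTF-8 CSV files:

``visits.csv``
    ``visit_id,animal_id,corner,start_s,end_s`` — one row per corner visit.
``nosepokes.csv``
    ``visit_id,side,time_s,duration_s,lick_count,lick_duration_s,door_opened``
    — nosepokes keyed to their enclosing visit; ``door_opened`` is 0/1.
``flags.csv``
    ``time_s,subsystem,message`` — hardware fault markers.
``animals.csv``
    ``animal_id,tag,group_label,cohort_id,cage_id``.
``meta.csv`` (optional)
    ``key,value`` rows; currently ``t0_clock`` (wall-clock ``HH:MM`` at
    experiment time zero, default ``12:00``).

Timestamps are seconds since experiment start (float); all intervals are
half-open ``[start, end)``. Visits are atomic records — reconstruction from
raw antenna pings is out of scope.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "AnimalRecord",
    "NosepokeEvent",
    "VisitEvent",
    "HardwareFlag",
    "EventLog",
    "read_event_log",
    "write_event_log",
    "merge_logs",
    "validate_log",
]

VALID_CORNERS = (1, 2, 3, 4)
VALID_SIDES = ("left", "right")


class EventLogError(ValueError):
    """Raised for malformed files or invariant violations during parsing."""


@dataclass(frozen=True)
class AnimalRecord:
    """One transponder-tagged animal."""

    animal_id: str
    tag: str
    group_label: str
    cohort_id: str = "cohort0"
    cage_id: str = "cage0"


@dataclass(frozen=True)
class NosepokeEvent:
    """A beam-break response at one bottle opening inside a corner.

    ``lick_count``/``lick_duration_s`` quantify drinking; licks require the
    door to have opened.
    """

    side: str
    time_s: float
    duration_s: float = 0.0
    lick_count: int = 0
    lick_duration_s: float = 0.0
    door_opened: bool = False


@dataclass(frozen=True)
class VisitEvent:
    """One entry-to-exit episode of an animal in a corner chamber."""

    visit_id: int
    animal_id: str
    corner: int
    start_s: float
    end_s: float
    nosepokes: tuple[NosepokeEvent, ...] = ()


@dataclass(frozen=True)
class HardwareFlag:
    """A fault marker emitted by a cage subsystem."""

    time_s: float
    subsystem: str
    message: str


@dataclass(frozen=True)
class EventLog:
    """A validated, time-ordered record of one cage's events.

    ``visits`` are sorted by start time; per corner, visits of different
    animals never overlap (the chamber admits a single mouse at a time).
    ``t0_clock`` is the wall-clock ``HH:MM`` corresponding to ``t = 0``.
    """

    animals: tuple[AnimalRecord, ...]
    visits: tuple[VisitEvent, ...]
    flags: tuple[HardwareFlag, ...] = ()
    t0_clock: str = "12:00"

    @property
    def cage_id(self) -> str:
        return self.animals[0].cage_id if self.animals else "cage0"

    def span(self) -> tuple[float, float]:
        """(first event start, last event end); (0, 0) if empty."""
        if not self.visits:
            return (0.0, 0.0)
        return (self.visits[0].start_s, max(v.end_s for v in self.visits))


def _fmt(x: float) -> str:
    # repr() is the shortest round-trip representation, so
    # write -> read -> write is byte-stable.
    return repr(float(x))


def _parse_float(s: str, path: Path, line: int, col: str) -> float:
    try:
        return float(s)
    except ValueError:
        raise EventLogError(f"{path}, line {line}: bad {col} value {s!r}") from None


def _parse_int(s: str, path: Path, line: int, col: str) -> int:
    try:
        return int(s)
    except ValueError:
        raise EventLogError(f"{path}, line {line}: bad {col} value {s!r}") from None


def _read_rows(path: Path, header: Sequence[str]) -> list[tuple[int, dict]]:
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            got = next(reader)
        except StopIteration:
            raise EventLogError(f"{path}: empty file, expected header {','.join(header)}")
        if got != list(header):
            raise EventLogError(
                f"{path}: bad header {','.join(got)!r}, expected {','.join(header)!r}"
            )
        rows = []
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(header):
                raise EventLogError(
                    f"{path}, line {lineno}: expected {len(header)} fields, got {len(row)}"
                )
            rows.append((lineno, dict(zip(header, row))))
    return rows


def read_event_log(path: str | Path, strict: bool = True) -> EventLog:
    """Load a validated :class:`EventLog` from a CSV dialect directory.

    Parsing is lossless: ``write_event_log`` followed by ``read_event_log``
    reproduces the log exactly, and re-writing reproduces the files
    byte-for-byte. With ``strict=False`` the final whole-log invariant
    check is skipped (row-level parsing errors still raise), so the caller
    can collect violations with :func:`validate_log` instead.

    Raises
    ------
    EventLogError
        For malformed rows (naming the file and line), duplicate transponder
        tags, invariant violations (e.g. ``end_s <= start_s``), or nosepokes
        out of time order within a visit.
    """
    path = Path(path)
    animals_rows = _read_rows(
        path / "animals.csv", ["animal_id", "tag", "group_label", "cohort_id", "cage_id"]
    )
    animals = []
    seen_ids: set[str] = set()
    seen_tags: set[tuple[str, str]] = set()
    for lineno, r in animals_rows:
        if r["animal_id"] in seen_ids:
            raise EventLogError(
                f"{path / 'animals.csv'}, line {lineno}: duplicate animal_id {r['animal_id']!r}"
            )
        key = (r["cage_id"], r["tag"])
        if key in seen_tags:
            raise EventLogError(
                f"{path / 'animals.csv'}, line {lineno}: duplicate tag {r['tag']!r} in cage {r['cage_id']!r}"
            )
        seen_ids.add(r["animal_id"])
        seen_tags.add(key)
        animals.append(AnimalRecord(**r))

    poke_rows = _read_rows(
        path / "nosepokes.csv",
        ["visit_id", "side", "time_s", "duration_s", "lick_count", "lick_duration_s", "door_opened"],
    )
    pokes_by_visit: dict[int, list[NosepokeEvent]] = {}
    pfile = path / "nosepokes.csv"
    for lineno, r in poke_rows:
        if r["side"] not in VALID_SIDES:
            raise EventLogError(f"{pfile}, line {lineno}: bad side {r['side']!r}")
        poke = NosepokeEvent(
            side=r["side"],
            time_s=_parse_float(r["time_s"], pfile, lineno, "time_s"),
            duration_s=_parse_float(r["duration_s"], pfile, lineno, "duration_s"),
            lick_count=_parse_int(r["lick_count"], pfile, lineno, "lick_count"),
            lick_duration_s=_parse_float(r["lick_duration_s"], pfile, lineno, "lick_duration_s"),
            door_opened=r["door_opened"] == "1",
        )
        vid = _parse_int(r["visit_id"], pfile, lineno, "visit_id")
        pokes_by_visit.setdefault(vid, []).append(poke)

    visit_rows = _read_rows(
        path / "visits.csv", ["visit_id", "animal_id", "corner", "start_s", "end_s"]
    )
    vfile = path / "visits.csv"
    visits = []
    for lineno, r in visit_rows:
        vid = _parse_int(r["visit_id"], vfile, lineno, "visit_id")
        corner = _parse_int(r["corner"], vfile, lineno, "corner")
        start = _parse_float(r["start_s"], vfile, lineno, "start_s")
        end = _parse_float(r["end_s"], vfile, lineno, "end_s")
        if corner not in VALID_CORNERS:
            raise EventLogError(f"{vfile}, line {lineno}: corner {corner} not in 1-4")
        if end <= start:
            raise EventLogError(
                f"{vfile}, line {lineno}: end_s {end} not after start_s {start}"
            )
        if r["animal_id"] not in seen_ids:
            raise EventLogError(
                f"{vfile}, line {lineno}: unknown animal_id {r['animal_id']!r}"
            )
        pokes = tuple(pokes_by_visit.pop(vid, ()))
        times = [p.time_s for p in pokes]
        if any(t2 < t1 for t1, t2 in zip(times, times[1:])):
            raise EventLogError(
                f"{vfile}, line {lineno}: nosepoke times of visit {vid} not in time order"
            )
        for p in pokes:
            if not (start <= p.time_s < end):
                raise EventLogError(
                    f"{vfile}, line {lineno}: nosepoke at t={p.time_s} outside visit "
                    f"[{start}, {end})"
                )
        visits.append(VisitEvent(vid, r["animal_id"], corner, start, end, pokes))
    if pokes_by_visit:
        orphan = sorted(pokes_by_visit)[0]
        raise EventLogError(f"{pfile}: nosepokes reference unknown visit_id {orphan}")

    flag_rows = _read_rows(path / "flags.csv", ["time_s", "subsystem", "message"])
    ffile = path / "flags.csv"
    flags = tuple(
        HardwareFlag(_parse_float(r["time_s"], ffile, lineno, "time_s"), r["subsystem"], r["message"])
        for lineno, r in flag_rows
    )

    t0_clock = "12:00"
    meta_path = path / "meta.csv"
    if meta_path.exists():
        for _, r in _read_rows(meta_path, ["key", "value"]):
            if r["key"] == "t0_clock":
                t0_clock = r["value"]

    visits.sort(key=lambda v: (v.start_s, v.visit_id))
    log = EventLog(tuple(animals), tuple(visits), flags, t0_clock)
    if strict:
        problems = validate_log(log)
        if problems:
            raise EventLogError(f"{path}: invalid log: {problems[0]}")
    return log


def write_event_log(log: EventLog, path: str | Path) -> None:
    """Write ``log`` to ``path`` in the canonical CSV dialect.

    Output is deterministic and canonical: reading it back and re-writing
    produces byte-identical files.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    with open(path / "animals.csv", "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["animal_id", "tag", "group_label", "cohort_id", "cage_id"])
        for a in log.animals:
            w.writerow([a.animal_id, a.tag, a.group_label, a.cohort_id, a.cage_id])

    with open(path / "visits.csv", "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["visit_id", "animal_id", "corner", "start_s", "end_s"])
        for v in log.visits:
            w.writerow([v.visit_id, v.animal_id, v.corner, _fmt(v.start_s), _fmt(v.end_s)])

    with open(path / "nosepokes.csv", "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(
            ["visit_id", "side", "time_s", "duration_s", "lick_count", "lick_duration_s", "door_opened"]
        )
        for v in log.visits:
            for p in v.nosepokes:
                w.writerow(
                    [
                        v.visit_id,
                        p.side,
                        _fmt(p.time_s),
                        _fmt(p.duration_s),
                        p.lick_count,
                        _fmt(p.lick_duration_s),
                        int(p.door_opened),
                    ]
                )

    with open(path / "flags.csv", "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["time_s", "subsystem", "message"])
        for f in log.flags:
            w.writerow([_fmt(f.time_s), f.subsystem, f.message])

    with open(path / "meta.csv", "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["key", "value"])
        w.writerow(["t0_clock", log.t0_clock])


def merge_logs(logs: Sequence[EventLog]) -> EventLog:
    """Merge several logs of the same cage into one time-sorted log.

    Inputs must share ``cage_id`` and ``t0_clock``. Visit ids are
    reassigned sequentially in time order; the total visit count is
    conserved. Raises :class:`EventLogError` if the concatenation violates
    single occupancy (conflicting events for one corner in overlapping
    time ranges).
    """
    if not logs:
        raise EventLogError("merge_logs: no logs given")
    if len(logs) == 1:
        return logs[0]
    cages = {lg.cage_id for lg in logs}
    if len(cages) > 1:
        raise EventLogError(f"merge_logs: logs from different cages {sorted(cages)}")
    t0s = {lg.t0_clock for lg in logs}
    if len(t0s) > 1:
        raise EventLogError(f"merge_logs: logs with different t0_clock {sorted(t0s)}")

    animals: dict[str, AnimalRecord] = {}
    for lg in logs:
        for a in lg.animals:
            if a.animal_id in animals and animals[a.animal_id] != a:
                raise EventLogError(
                    f"merge_logs: conflicting records for animal {a.animal_id!r}"
                )
            animals[a.animal_id] = a

    visits = sorted(
        (v for lg in logs for v in lg.visits), key=lambda v: (v.start_s, v.animal_id)
    )
    visits = tuple(
        replace(v, visit_id=i) for i, v in enumerate(visits)
    )
    flags = tuple(sorted((f for lg in logs for f in lg.flags), key=lambda f: f.time_s))
    merged = EventLog(tuple(animals.values()), visits, flags, logs[0].t0_clock)
    problems = [p for p in validate_log(merged) if "single-occupancy" in p]
    if problems:
        raise EventLogError(f"merge_logs: {problems[0]}")
    return merged


def validate_log(log: EventLog) -> list[str]:
    """Check every EventLog invariant; return violation descriptions.

    Returns an empty list iff the log is valid. Never raises and never
    mutates the log. Each violation names the rule and, where applicable,
    the time and animal involved.
    """
    problems: list[str] = []
    ids = [a.animal_id for a in log.animals]
    if len(ids) != len(set(ids)):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        problems.append(f"duplicate-animal-id: {dup}")
    tags: dict[tuple[str, str], str] = {}
    for a in log.animals:
        key = (a.cage_id, a.tag)
        if key in tags:
            problems.append(
                f"duplicate-tag: tag {a.tag!r} shared by {tags[key]!r} and {a.animal_id!r}"
            )
        tags[key] = a.animal_id
    known = set(ids)

    prev_start = float("-inf")
    for v in log.visits:
        if v.start_s < prev_start:
            problems.append(
                f"visit-order: visit {v.visit_id} at t={v.start_s} out of order"
            )
        prev_start = v.start_s
        if v.animal_id not in known:
            problems.append(
                f"unknown-animal: visit {v.visit_id} references {v.animal_id!r}"
            )
        if v.corner not in VALID_CORNERS:
            problems.append(f"corner-range: visit {v.visit_id} corner {v.corner}")
        if not v.end_s > v.start_s:
            problems.append(
                f"visit-span: visit {v.visit_id} of {v.animal_id} has end {v.end_s} <= start {v.start_s}"
            )
        for p in v.nosepokes:
            if not (v.start_s <= p.time_s < v.end_s):
                problems.append(
                    f"containment: nosepoke at t={p.time_s} outside visit {v.visit_id} "
                    f"[{v.start_s}, {v.end_s}) of {v.animal_id}"
                )
            if p.lick_count == 0 and p.lick_duration_s != 0:
                problems.append(
                    f"lick-duration: nosepoke at t={p.time_s} of {v.animal_id} has "
                    f"lick_duration {p.lick_duration_s} with zero licks"
                )
            if p.lick_count > 0 and not p.door_opened:
                problems.append(
                    f"lick-door: nosepoke at t={p.time_s} of {v.animal_id} has licks "
                    "with door closed"
                )
            if p.duration_s < 0 or p.lick_count < 0 or p.lick_duration_s < 0:
                problems.append(
                    f"negative-field: nosepoke at t={p.time_s} of {v.animal_id}"
                )

    # single occupancy per corner: intervals of different animals may not overlap
    by_corner: dict[int, list[VisitEvent]] = {}
    for v in log.visits:
        by_corner.setdefault(v.corner, []).append(v)
    for corner, vs in sorted(by_corner.items()):
        busy_until = float("-inf")
        prev: VisitEvent | None = None
        for v in sorted(vs, key=lambda x: x.start_s):
            if prev is not None and v.start_s < busy_until and v.animal_id != prev.animal_id:
                problems.append(
                    f"single-occupancy: corner {corner} at t={v.start_s}: "
                    f"{v.animal_id} entered while {prev.animal_id} present"
                )
            if v.end_s > busy_until:
                busy_until = v.end_s
                prev = v

    for f in log.flags:
        if f.time_s < 0:
            problems.append(f"flag-time: flag {f.message!r} at negative t={f.time_s}")
    return problems
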