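"""Per-animal, per-bin behavioral measures from a screened event log.

Events are analyzed in 12-h time bins (6-h supported) aligned to the
light-dark cycle, each bin lying wholly within one light or dark phase.
An event belongs to the bin containing its *start* time; visits spanning a
boundary are not split. Bins whose denominator is zero, or that intersect
an exclusion interval, are *missing* — a mouse that never visited is not
"0% correct".

Metric tables are long-format pandas DataFrames with columns
``animal_id, bin_index, bin_start_s, ld_label, metric_name, value``
(``value`` is NaN when missing). Percentage metrics live in [0, 100].
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from cagewalk.events_io import EventLog
from cagewalk.protocol import (
    LightDarkCycle,
    ProtocolSchedule,
    ld_phase,
    ld_transitions_before,
)
from cagewalk.screening import ExclusionInterval, apply_exclusions

__all__ = [
    "BinGrid",
    "BinnedCounts",
    "grid_for_phase",
    "bin_events",
    "pct_correct",
    "pct_perseverative",
    "activity_summary",
    "corner_distribution",
    "lick_preference",
    "visit_durations",
]

TABLE_COLUMNS = ["animal_id", "bin_index", "bin_start_s", "ld_label", "metric_name", "value"]


@dataclass(frozen=True)
class BinGrid:
    """Contiguous equal-width half-open time bins ``[origin + i*w, origin + (i+1)*w)``.

    ``origin_s`` should sit on a light-dark transition so that default
    12-h bins coincide with light/dark phases. ``origin_s`` may be
    negative (when the anchoring transition precedes experiment start).
    """

    bin_width_s: float = 43200.0
    origin_s: float = 0.0
    n_bins: int = 26

    def __post_init__(self) -> None:
        if self.bin_width_s <= 0:
            raise ValueError("bin_width_s must be positive")
        if self.n_bins <= 0:
            raise ValueError("n_bins must be positive")

    @classmethod
    def cover(
        cls, start_s: float, end_s: float, bin_width_s: float = 43200.0, origin_s: float = 0.0
    ) -> "BinGrid":
        """Smallest grid anchored at ``origin_s`` covering ``[start_s, end_s)``."""
        first = math.floor((start_s - origin_s) / bin_width_s)
        last = math.ceil((end_s - origin_s) / bin_width_s)
        if last <= first:
            last = first + 1
        return cls(bin_width_s, origin_s + first * bin_width_s, last - first)

    @property
    def end_s(self) -> float:
        return self.origin_s + self.n_bins * self.bin_width_s

    def index(self, t_s: float) -> int:
        """Bin index of time ``t_s``; raises if outside the grid."""
        i = math.floor((t_s - self.origin_s) / self.bin_width_s)
        if not 0 <= i < self.n_bins:
            raise ValueError(f"t={t_s} outside grid [{self.origin_s}, {self.end_s})")
        return i

    def start(self, i: int) -> float:
        return self.origin_s + i * self.bin_width_s

    def floor(self, t_s: float) -> float:
        """Largest bin boundary <= t_s (grid arithmetic; not clipped)."""
        return self.origin_s + math.floor((t_s - self.origin_s) / self.bin_width_s) * self.bin_width_s

    def ceil(self, t_s: float) -> float:
        """Smallest bin boundary >= t_s."""
        return self.origin_s + math.ceil((t_s - self.origin_s) / self.bin_width_s) * self.bin_width_s

    def bins(self) -> list[tuple[float, float]]:
        return [(self.start(i), self.start(i + 1)) for i in range(self.n_bins)]


def grid_for_phase(
    schedule: ProtocolSchedule,
    t0_clock: str,
    phase_name: str | None = None,
    bin_width_s: float = 43200.0,
) -> BinGrid:
    """Bin grid for one phase (or the whole protocol).

    The grid origin is anchored at the light-dark transition at or before
    the start of the span being analyzed, so each default-width bin lies
    wholly within one light or dark phase.
    """
    if phase_name is None:
        start_s, end_s = 0.0, schedule.total_s
    else:
        ph = schedule.phase(phase_name)
        start_s, end_s = ph.start_s, ph.end_s
    anchor = ld_transitions_before(start_s, t0_clock, schedule.cycle)
    return BinGrid.cover(start_s, end_s, bin_width_s, anchor)


@dataclass(frozen=True)
class BinnedCounts:
    """Per-animal, per-bin, per-corner event counts.

    ``counts`` columns: ``animal_id, bin_index, corner, visits, nosepokes,
    licks, visit_duration_s``. ``excluded_bins`` lists bin indices that
    intersect an exclusion interval; metrics built from this object emit
    NaN for those bins. ``dropped`` is the number of visits removed by the
    exclusions before binning (kept + dropped = original total).
    """

    counts: pd.DataFrame
    grid: BinGrid
    ld_labels: tuple[str, ...]
    excluded_bins: frozenset[int]
    dropped: int
    phase: str | None = None
    animal_ids: tuple[str, ...] = ()

    def totals(self, event_kind: str = "visits") -> pd.DataFrame:
        """animal_id x bin_index totals over all corners (wide, 0-filled)."""
        pv = self.counts.pivot_table(
            index="animal_id", columns="bin_index", values=event_kind,
            aggfunc="sum", fill_value=0,
        )
        return pv.reindex(
            index=list(self.animal_ids), columns=range(self.grid.n_bins), fill_value=0
        )

    def corner_totals(self, corners: Mapping[str, int], event_kind: str = "visits") -> pd.DataFrame:
        """animal_id x bin_index totals restricted to each animal's own corner."""
        df = self.counts
        mask = df.apply(lambda r: corners.get(r["animal_id"]) == r["corner"], axis=1)
        sub = df[mask] if len(df) else df
        pv = sub.pivot_table(
            index="animal_id", columns="bin_index", values=event_kind,
            aggfunc="sum", fill_value=0,
        )
        return pv.reindex(
            index=list(self.animal_ids), columns=range(self.grid.n_bins), fill_value=0
        )


def bin_events(
    log: EventLog,
    grid: BinGrid,
    exclusions: Sequence[ExclusionInterval] = (),
    schedule: ProtocolSchedule | None = None,
    phase: str | None = None,
) -> BinnedCounts:
    """Count visits, nosepokes, licks and visit durations per animal/bin/corner.

    Events are assigned to the bin containing their start time. Events
    inside an exclusion interval are dropped first, and any bin
    intersecting an exclusion interval is marked excluded (missing
    downstream). When ``phase`` is None the grid must cover every
    remaining event; with a named phase, events outside the grid belong
    to other phases and are simply out of the analysis window.
    """
    screened, dropped = apply_exclusions(log, list(exclusions))
    lo, hi = screened.span()
    if phase is None and screened.visits and (lo < grid.origin_s or hi > grid.end_s):
        raise ValueError(
            f"grid [{grid.origin_s}, {grid.end_s}) does not cover log span [{lo}, {hi}]"
        )
    rows = []
    for v in screened.visits:
        if not grid.origin_s <= v.start_s < grid.end_s:
            continue
        b = grid.index(v.start_s)
        rows.append(
            (
                v.animal_id,
                b,
                v.corner,
                1,
                len(v.nosepokes),
                sum(p.lick_count for p in v.nosepokes),
                v.end_s - v.start_s,
            )
        )
    counts = pd.DataFrame(
        rows,
        columns=["animal_id", "bin_index", "corner", "visits", "nosepokes", "licks", "visit_duration_s"],
    )
    if len(counts):
        counts = (
            counts.groupby(["animal_id", "bin_index", "corner"], as_index=False).sum()
        )

    excluded = set()
    for iv in exclusions:
        for i in range(grid.n_bins):
            if iv.start_s < grid.start(i + 1) and iv.end_s > grid.start(i):
                excluded.add(i)

    cycle = schedule.cycle if schedule is not None else LightDarkCycle()
    mids = [grid.start(i) + grid.bin_width_s / 2 for i in range(grid.n_bins)]
    labels = tuple(ld_phase(m, log.t0_clock, cycle) for m in mids)

    return BinnedCounts(
        counts=counts,
        grid=grid,
        ld_labels=labels,
        excluded_bins=frozenset(excluded),
        dropped=dropped,
        phase=phase,
        animal_ids=tuple(a.animal_id for a in log.animals),
    )


def _table(counts: BinnedCounts, values: pd.DataFrame, metric_name: str) -> pd.DataFrame:
    rows = []
    for aid in counts.animal_ids:
        for b in range(counts.grid.n_bins):
            v = values.at[aid, b]
            if b in counts.excluded_bins:
                v = np.nan
            rows.append(
                (aid, b, counts.grid.start(b), counts.ld_labels[b], metric_name, v)
            )
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)


def _pct_of_corner(
    counts: BinnedCounts, corner_map: Mapping[str, int], event_kind: str, metric_name: str
) -> pd.DataFrame:
    missing = [a for a in counts.animal_ids if a not in corner_map]
    if missing:
        raise ValueError(f"corner map does not cover animals {missing}")
    total = counts.totals(event_kind).astype(float)
    target = counts.corner_totals(corner_map, event_kind).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = 100.0 * target / total.where(total > 0)
    return _table(counts, pct, metric_name)


def pct_correct(
    counts: BinnedCounts, reward_map: Mapping[str, int], event_kind: str = "visits"
) -> pd.DataFrame:
    """Percentage of correct responses per animal per bin.

    100 x (events in the animal's rewarded corner) / (events in all four
    corners); NaN where the animal made no events in the bin or the bin is
    excluded. ``event_kind`` selects visits or nosepokes (the two give very
    similar patterns; visits are the default report).
    """
    return _pct_of_corner(counts, reward_map, event_kind, f"pct_correct_{event_kind}")


def pct_perseverative(
    counts: BinnedCounts,
    previous_reward_map: Mapping[str, int],
    event_kind: str = "visits",
) -> pd.DataFrame:
    """Percentage of responses to the *previously* rewarded corner.

    The perseveration measure: during reversal training, the share of
    events still directed at the corner rewarded during place-preference
    learning. Only meaningful on reversal-phase bins; ``counts`` must have
    been binned with ``phase="reversal"``.
    """
    if counts.phase != "reversal":
        raise ValueError(
            f"pct_perseverative requires reversal-phase counts, got phase={counts.phase!r}"
        )
    return _pct_of_corner(
        counts, previous_reward_map, event_kind, f"pct_perseverative_{event_kind}"
    )


def activity_summary(
    counts: BinnedCounts, groups: Mapping[str, str], event_kind: str = "visits"
) -> pd.DataFrame:
    """Per-group mean +/- s.e.m. of total events per animal, split by light/dark.

    The activity control: group differences in overall corner visiting
    would confound percentage measures. s.e.m. = sd/sqrt(n) with sample sd
    (ddof=1); NaN for groups of one animal. Excluded bins do not
    contribute.
    """
    missing = [a for a in counts.animal_ids if a not in groups]
    if missing:
        raise ValueError(f"groups do not cover animals {missing}")
    totals = counts.totals(event_kind)
    keep = [b for b in range(counts.grid.n_bins) if b not in counts.excluded_bins]
    rows = []
    for label in ("dark", "light"):
        bins = [b for b in keep if counts.ld_labels[b] == label]
        per_animal = totals[bins].sum(axis=1)
        df = pd.DataFrame(
            {"total": per_animal, "group": [groups[a] for a in per_animal.index]}
        )
        for g, sub in df.groupby("group", sort=True):
            n = len(sub)
            mean = float(sub["total"].mean())
            sem = float(sub["total"].std(ddof=1) / math.sqrt(n)) if n >= 2 else np.nan
            rows.append((g, label, n, mean, sem))
    return pd.DataFrame(rows, columns=["group", "ld_label", "n", "mean", "sem"])


def corner_distribution(counts: BinnedCounts) -> pd.DataFrame:
    """Per-animal percentage of visits to each of the four corners.

    Computed over all non-excluded bins of ``counts`` (pass
    adaptation-phase counts to test for restricted exploration patterns).
    The four percentages sum to 100 for any animal with at least one
    visit; all four are NaN otherwise.
    """
    df = counts.counts
    keep = df[~df["bin_index"].isin(counts.excluded_bins)] if len(df) else df
    per = (
        keep.groupby(["animal_id", "corner"])["visits"].sum()
        if len(keep)
        else pd.Series(dtype=float)
    )
    rows = []
    for aid in counts.animal_ids:
        by_corner = np.array(
            [per.get((aid, c), 0) for c in (1, 2, 3, 4)], dtype=float
        )
        total = by_corner.sum()
        pcts = 100.0 * by_corner / total if total > 0 else np.full(4, np.nan)
        for c, p in zip((1, 2, 3, 4), pcts):
            rows.append((aid, c, p))
    return pd.DataFrame(rows, columns=["animal_id", "corner", "pct_visits"])


def lick_preference(
    log: EventLog,
    schedule: ProtocolSchedule,
    exclusions: Sequence[ExclusionInterval] = (),
    bin_width_s: float = 43200.0,
) -> pd.DataFrame:
    """Paired water vs sucrose lick totals per animal, per light/dark label.

    The motivation control: water intake is measured in the *last* dark and
    last light bin of nosepoke adaptation (tap water everywhere), sucrose
    intake in the *first* dark and first light bin of place preference (10%
    sucrose at the rewarded corner). Returns columns ``animal_id,
    ld_label, water_licks, sucrose_licks``; a value is NaN when its bin is
    excluded.
    """
    out_rows = []
    picks: dict[tuple[str, str], dict[str, float]] = {}
    for phase_name, col, which in (
        ("nosepoke_adaptation", "water_licks", "last"),
        ("place_preference", "sucrose_licks", "first"),
    ):
        grid = grid_for_phase(schedule, log.t0_clock, phase_name, bin_width_s)
        ph = schedule.phase(phase_name)
        counts = bin_events(log, grid, exclusions, schedule, phase_name)
        licks = counts.totals("licks")
        # bins wholly inside the phase
        inside = [
            b
            for b in range(grid.n_bins)
            if grid.start(b) >= ph.start_s - 1e-9 and grid.start(b + 1) <= ph.end_s + 1e-9
        ]
        for label in ("dark", "light"):
            cands = [b for b in inside if counts.ld_labels[b] == label]
            if not cands:
                continue
            b = max(cands) if which == "last" else min(cands)
            for aid in counts.animal_ids:
                val = np.nan if b in counts.excluded_bins else float(licks.at[aid, b])
                picks.setdefault((aid, label), {})[col] = val
    for (aid, label), d in sorted(picks.items()):
        out_rows.append(
            (aid, label, d.get("water_licks", np.nan), d.get("sucrose_licks", np.nan))
        )
    return pd.DataFrame(
        out_rows, columns=["animal_id", "ld_label", "water_licks", "sucrose_licks"]
    )


def visit_durations(counts: BinnedCounts) -> pd.DataFrame:
    """Cumulative visit duration per animal per bin (seconds).

    Exported for completeness but excluded from the default report: visit
    duration is a labile, poorly replicable parameter compared with visit
    and nosepoke counts.
    """
    dur = counts.counts.pivot_table(
        index="animal_id", columns="bin_index", values="visit_duration_s",
        aggfunc="sum", fill_value=0.0,
    ).reindex(index=list(counts.animal_ids), columns=range(counts.grid.n_bins), fill_value=0.0)
    return _table(counts, dur, "visit_duration_s")
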