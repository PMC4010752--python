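"""Training protocol, light-dark cycle, corner assignment and fear schedules.

The default home-cage protocol runs continuously for 13 days in four
contiguous phases:

==================== ======== ==========================================
phase                duration door / reward policy
==================== ======== ==========================================
simple_adaptation    5 d      all doors open, water everywhere
nosepoke_adaptation  2 d      doors nosepoke-operated, water everywhere
place_preference     3 d      10% sucrose in one randomly assigned corner
reversal             3 d      reward moved to the diagonally opposite corner
==================== ======== ==========================================

All durations are overridable. "Opposite corner" is taken as the diagonal
corner under a numbering where corners 1,2 share one cage wall (1<->3,
2<->4); the convention is configurable via ``reversal_map``'s ``mapping``
argument.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from cagewalk.events_io import AnimalRecord, VALID_CORNERS

__all__ = [
    "LightDarkCycle",
    "PhaseSpec",
    "ProtocolSchedule",
    "build_schedule",
    "assign_corners",
    "reversal_map",
    "ld_phase",
    "FearStimulus",
    "FearSchedule",
    "build_fear_schedule",
    "DEFAULT_PHASE_DAYS",
]

DAY_S = 86400.0
PHASE_NAMES = ("simple_adaptation", "nosepoke_adaptation", "place_preference", "reversal")
DEFAULT_PHASE_DAYS: dict[str, float] = {
    "simple_adaptation": 5.0,
    "nosepoke_adaptation": 2.0,
    "place_preference": 3.0,
    "reversal": 3.0,
}
REWARD_PHASES = ("place_preference", "reversal")


def _clock_to_s(clock: str) -> float:
    """Parse 'HH:MM' into seconds past midnight."""
    try:
        hh, mm = clock.split(":")
        s = int(hh) * 3600.0 + int(mm) * 60.0
    except (ValueError, AttributeError):
        raise ValueError(f"bad clock time {clock!r}, expected 'HH:MM'") from None
    if not 0 <= s < DAY_S:
        raise ValueError(f"clock time {clock!r} out of range")
    return s


@dataclass(frozen=True)
class LightDarkCycle:
    """A 24-h periodic illumination schedule.

    ``dark_onset_clock`` is the wall-clock time the lights go off (the
    animal facility here runs a shifted cycle with dark 13:00-01:00, so the
    animals' active period falls in the experimenter's working day).
    """

    dark_onset_clock: str = "13:00"
    dark_hours: float = 12.0

    def __post_init__(self) -> None:
        _clock_to_s(self.dark_onset_clock)
        if not 0 < self.dark_hours < 24:
            raise ValueError(f"dark_hours must be in (0, 24), got {self.dark_hours}")


def ld_phase(t_s: float, t0_clock: str, cycle: LightDarkCycle) -> str:
    """Label experiment time ``t_s`` as ``'light'`` or ``'dark'``.

    Handles dark phases that wrap across midnight (e.g. 13:00-01:00).
    Periodic: ``ld_phase(t) == ld_phase(t + 86400)``.
    """
    clock = (_clock_to_s(t0_clock) + t_s) % DAY_S
    onset = _clock_to_s(cycle.dark_onset_clock)
    since_onset = (clock - onset) % DAY_S
    return "dark" if since_onset < cycle.dark_hours * 3600.0 else "light"


def ld_transitions_before(t_s: float, t0_clock: str, cycle: LightDarkCycle) -> float:
    """Latest light-dark (or dark-light) transition at or before ``t_s``.

    May be negative if the first transition after experiment start lies
    ahead of ``t_s``. Used to anchor analysis bin grids.
    """
    t0 = _clock_to_s(t0_clock)
    onset = _clock_to_s(cycle.dark_onset_clock)
    offset = (onset + cycle.dark_hours * 3600.0) % DAY_S
    candidates = []
    for mark in (onset, offset):
        # transition experiment-times are mark - t0 (mod 24 h)
        first = (mark - t0) % DAY_S
        k = np.floor((t_s - first) / DAY_S)
        candidates.append(first + k * DAY_S)
    return max(candidates)


@dataclass(frozen=True)
class PhaseSpec:
    """One contiguous training phase."""

    name: str
    start_day: float
    duration_days: float
    door_policy: str  # "open" | "nosepoke_operated"
    reward_map: Mapping[str, int] | None = None
    reward_liquid: str = "water"  # "water" | "sucrose_10pct"

    @property
    def start_s(self) -> float:
        return self.start_day * DAY_S

    @property
    def end_s(self) -> float:
        return (self.start_day + self.duration_days) * DAY_S


@dataclass(frozen=True)
class ProtocolSchedule:
    """The full multi-phase protocol plus the light-dark cycle."""

    phases: tuple[PhaseSpec, ...]
    cycle: LightDarkCycle
    total_days: float

    @property
    def total_s(self) -> float:
        return self.total_days * DAY_S

    def phase_at(self, t_s: float) -> PhaseSpec | None:
        for ph in self.phases:
            if ph.start_s <= t_s < ph.end_s:
                return ph
        return None

    def phase(self, name: str) -> PhaseSpec:
        for ph in self.phases:
            if ph.name == name:
                return ph
        raise KeyError(f"no phase named {name!r}")


def build_schedule(
    durations_days: Mapping[str, float] | None = None,
    cycle: LightDarkCycle | None = None,
    reward_map: Mapping[str, int] | None = None,
    total_days: float | None = None,
) -> ProtocolSchedule:
    """Build the four-phase schedule (defaults: 5 + 2 + 3 + 3 = 13 days).

    ``reward_map`` maps animal_id to the corner rewarded during place
    preference; the reversal phase automatically uses the diagonally
    opposite corner. If ``total_days`` is given it must equal the sum of
    phase durations.
    """
    days = dict(DEFAULT_PHASE_DAYS)
    if durations_days:
        unknown = set(durations_days) - set(PHASE_NAMES)
        if unknown:
            raise ValueError(f"unknown phase names {sorted(unknown)}")
        days.update(durations_days)
    for name, d in days.items():
        if d <= 0:
            raise ValueError(f"phase {name!r} has non-positive duration {d}")
    total = sum(days[n] for n in PHASE_NAMES)
    if total_days is not None and abs(total_days - total) > 1e-9:
        raise ValueError(
            f"declared total_days {total_days} != sum of phase durations {total}"
        )
    cycle = cycle or LightDarkCycle()
    rev_map = (
        {aid: reversal_map(c) for aid, c in reward_map.items()} if reward_map else None
    )
    phases = []
    start = 0.0
    for name in PHASE_NAMES:
        phases.append(
            PhaseSpec(
                name=name,
                start_day=start,
                duration_days=days[name],
                door_policy="open" if name == "simple_adaptation" else "nosepoke_operated",
                reward_map=(
                    reward_map if name == "place_preference"
                    else rev_map if name == "reversal"
                    else None
                ),
                reward_liquid="sucrose_10pct" if name in REWARD_PHASES else "water",
            )
        )
        start += days[name]
    return ProtocolSchedule(tuple(phases), cycle, total)


def assign_corners(
    animals: Sequence[AnimalRecord | str],
    n_corners: int = 4,
    cap: int = 3,
    seed: int = 0,
) -> dict[str, int]:
    """Randomly assign each animal a rewarded corner, at most ``cap`` per corner.

    Capped random assignment via seeded shuffle + round-robin: with 12
    animals on 4 corners every corner receives exactly 3. Reproducible
    given ``seed``.
    """
    ids = [a.animal_id if isinstance(a, AnimalRecord) else str(a) for a in animals]
    if len(ids) > cap * n_corners:
        raise ValueError(
            f"{len(ids)} animals exceed capacity {cap} x {n_corners} corners"
        )
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(len(ids)))
    corners = list(rng.permutation(np.arange(1, n_corners + 1)))
    return {ids[idx]: int(corners[i % n_corners]) for i, idx in enumerate(order)}


def reversal_map(corner: int, mapping: Mapping[int, int] | None = None) -> int:
    """Map a corner to its reversal ("opposite") corner: 1<->3, 2<->4.

    The default is the diagonal convention (fixed-point-free involution);
    pass ``mapping`` to override.
    """
    table = dict(mapping) if mapping else {1: 3, 3: 1, 2: 4, 4: 2}
    if corner not in VALID_CORNERS or corner not in table:
        raise ValueError(f"invalid corner {corner!r}")
    return table[corner]


@dataclass(frozen=True)
class FearStimulus:
    """A tone (CS) or footshock (US) presentation."""

    kind: str  # "CS" | "US"
    onset_s: float
    duration_s: float

    @property
    def offset_s(self) -> float:
        return self.onset_s + self.duration_s


@dataclass(frozen=True)
class FearSchedule:
    """Ordered CS/US timeline of one fear-conditioning session."""

    phase: str
    stimuli: tuple[FearStimulus, ...]
    duration_s: float

    @property
    def cs_events(self) -> tuple[FearStimulus, ...]:
        return tuple(s for s in self.stimuli if s.kind == "CS")

    @property
    def us_events(self) -> tuple[FearStimulus, ...]:
        return tuple(s for s in self.stimuli if s.kind == "US")


def build_fear_schedule(
    phase: str,
    baseline_s: float = 180.0,
    cs_duration_s: float = 20.0,
    us_duration_s: float = 1.0,
    iti_s: float = 60.0,
    tail_s: float = 30.0,
) -> FearSchedule:
    """Build the CS/US timeline for one session.

    * ``conditioning`` — 3-min baseline, then 5 tone-shock pairings (CS
      20 s, 85 dB 5 kHz; US 1 s 0.6 mA co-terminating with the tone),
      60-s intertrial intervals, 30-s tail.
    * ``extinction`` — 12 tones, no shocks, 60-s ITI.
    * ``test`` — 2 tones, no shocks, 60-s ITI.

    ITI is measured CS offset to next CS onset. The US co-terminates with
    its CS (ends when the tone ends).
    """
    n_cs = {"conditioning": 5, "extinction": 12, "test": 2}.get(phase)
    if n_cs is None:
        raise ValueError(
            f"unknown fear phase {phase!r}; expected conditioning/extinction/test"
        )
    with_us = phase == "conditioning"
    stimuli: list[FearStimulus] = []
    t = baseline_s
    for _ in range(n_cs):
        stimuli.append(FearStimulus("CS", t, cs_duration_s))
        if with_us:
            stimuli.append(
                FearStimulus("US", t + cs_duration_s - us_duration_s, us_duration_s)
            )
        t += cs_duration_s + iti_s
    duration = t - iti_s + tail_s
    return FearSchedule(phase, tuple(stimuli), duration)
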