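"""Agent-based synthetic cohort generator.

No public dataset of home-cage operant event logs accompanies this kind of
experiment, so every pipeline stage is exercised against simulated cohorts
with known ground truth. Each animal is a small reinforcement-learning
agent living on the real protocol clock:

* **activity** — visits arrive by an inhomogeneous Poisson process whose
  rate switches between ``lambda_dark`` and ``lambda_light`` with the
  light-dark cycle (mice are nocturnal; dark-phase activity dominates).
* **choice** — corners are chosen by a softmax over per-corner values
  ``(V_c + habit_gain * H_c) / tau``.
* **learning** — after each visit the chosen corner's value follows a
  delta rule ``V_c += alpha * (r - V_c)``, with reward ``r = 1`` iff the
  animal drank in its rewarded corner during a reward phase.
* **perseveration** — a habit trace ``H`` increments on the chosen corner
  and decays geometrically each visit; ``habit_gain`` scales its pull.
  ``alpha`` and ``habit_gain`` give separate "cognition" and "rigidity"
  axes that the metrics must dissociate.
* **single occupancy** — a visit aimed at an occupied corner is deferred
  by ~N(10 s, 2 s) rather than discarded, preserving per-animal rates.

The output always satisfies every :class:`~cagewalk.events_io.EventLog`
invariant and is bit-reproducible given the seed.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from cagewalk.events_io import (
    AnimalRecord,
    EventLog,
    HardwareFlag,
    NosepokeEvent,
    VisitEvent,
)
from cagewalk.fear_assay import FreezingTrace
from cagewalk.protocol import (
    ProtocolSchedule,
    _clock_to_s,
    assign_corners,
    build_fear_schedule,
    build_schedule,
)
from cagewalk.screening import ExclusionInterval

__all__ = [
    "SimConfig",
    "simulate_cohort",
    "simulate_freezing",
    "FearSimResult",
    "inject_corruption",
    "default_cohort",
]

DAY_S = 86400.0


@dataclass(frozen=True)
class SimConfig:
    """Generative parameters of a synthetic cohort.

    Rates are visits/hour/animal; defaults put dark-phase activity at 4x
    light-phase, with per-phase visit totals on the order of 10^2 per
    animal, comparable to real group means. ``alpha`` is the delta-rule
    learning rate; the default 0.02 makes acquisition unfold over days
    (as in real place-preference learning) rather than hours. ``tau`` is
    the softmax temperature (0.35 puts asymptotic accuracy near 85%, a
    realistic ceiling); ``habit_gain`` / ``habit_decay`` shape the
    perseverative habit trace, and ``sucrose_lick_multiplier`` the
    palatability boost of 10% sucrose over tap water.
    """

    n_animals: int = 12
    seed: int = 0
    lambda_dark: float = 6.0
    lambda_light: float = 1.5
    alpha: float = 0.02
    tau: float = 0.35
    habit_gain: float = 0.0
    habit_decay: float = 0.9
    sucrose_lick_multiplier: float = 4.0
    visit_duration_mean_s: float = 25.0
    visit_duration_shape: float = 2.0
    nosepoke_mean: float = 1.5
    lick_mean: float = 12.0
    group_label: str = "control"
    cohort_id: str = "cohort0"
    cage_id: str = "cage0"
    t0_clock: str = "13:00"  # start at dark onset: bins align with LD phases

    def validate(self) -> None:
        if self.n_animals < 1:
            raise ValueError("n_animals must be >= 1")
        if self.lambda_dark <= 0 or self.lambda_light <= 0:
            raise ValueError("activity rates must be positive")
        if not 0 <= self.alpha <= 1:
            raise ValueError("alpha must be in [0, 1]")
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.habit_gain < 0:
            raise ValueError("habit_gain must be >= 0")
        if not 0 <= self.habit_decay < 1:
            raise ValueError("habit_decay must be in [0, 1)")
        if self.sucrose_lick_multiplier <= 0:
            raise ValueError("sucrose_lick_multiplier must be positive")
        if self.visit_duration_mean_s <= 0 or self.visit_duration_shape <= 0:
            raise ValueError("visit duration parameters must be positive")
        _clock_to_s(self.t0_clock)


def _animal_records(config: SimConfig) -> list[AnimalRecord]:
    return [
        AnimalRecord(
            animal_id=f"m{i:02d}",
            tag=f"tag{i:03d}",
            group_label=config.group_label,
            cohort_id=config.cohort_id,
            cage_id=config.cage_id,
        )
        for i in range(config.n_animals)
    ]


def default_cohort(
    config: SimConfig, schedule_kwargs: dict | None = None
) -> tuple[list[AnimalRecord], ProtocolSchedule]:
    """Animals plus a default 13-day schedule with seeded corner assignment."""
    animals = _animal_records(config)
    reward_map = assign_corners(animals, seed=config.seed)
    schedule = build_schedule(reward_map=reward_map, **(schedule_kwargs or {}))
    return animals, schedule


def simulate_cohort(config: SimConfig, schedule: ProtocolSchedule) -> EventLog:
    """Simulate one cage of agents through the whole protocol.

    Every reward phase in ``schedule`` must carry a reward map covering
    all animals. Identical ``config`` + ``schedule`` always produce an
    identical log.
    """
    config.validate()
    animals = _animal_records(config)
    ids = [a.animal_id for a in animals]
    for ph in schedule.phases:
        if ph.name in ("place_preference", "reversal"):
            if ph.reward_map is None:
                raise ValueError(f"phase {ph.name!r} lacks a reward map")
            missing = [a for a in ids if a not in ph.reward_map]
            if missing:
                raise ValueError(f"reward map of {ph.name!r} misses animals {missing}")

    rng = np.random.default_rng(config.seed)
    T = schedule.total_s
    t0_s = _clock_to_s(config.t0_clock)
    onset_s = _clock_to_s(schedule.cycle.dark_onset_clock)
    dark_s = schedule.cycle.dark_hours * 3600.0

    lam_dark = config.lambda_dark / 3600.0
    lam_light = config.lambda_light / 3600.0
    lam_max = max(lam_dark, lam_light)

    def rate(t: float) -> float:
        since_onset = (t0_s + t - onset_s) % DAY_S
        return lam_dark if since_onset < dark_s else lam_light

    def next_arrival(t: float) -> float | None:
        # thinning: exact inhomogeneous Poisson with piecewise-constant rate
        while True:
            t += rng.exponential(1.0 / lam_max)
            if t >= T:
                return None
            if rng.random() * lam_max < rate(t):
                return t

    n = config.n_animals
    V = np.zeros((n, 4))
    H = np.zeros((n, 4))
    busy_until = np.zeros(4)

    heap: list[tuple[float, int]] = []
    for i in range(n):
        t = next_arrival(0.0)
        if t is not None:
            heapq.heappush(heap, (t, i))

    raw_visits: list[tuple[float, float, int, int, tuple[NosepokeEvent, ...]]] = []

    while heap:
        t, i = heapq.heappop(heap)
        phase = schedule.phase_at(t)
        if phase is None:  # past protocol end (numerical edge)
            continue
        logits = (V[i] + config.habit_gain * H[i]) / config.tau
        logits -= logits.max()
        p = np.exp(logits)
        p /= p.sum()
        corner = int(np.searchsorted(np.cumsum(p), rng.random()) + 1)

        if busy_until[corner - 1] > t:
            # occupied: defer and retry
            t2 = t + abs(rng.normal(10.0, 2.0))
            if t2 < T:
                heapq.heappush(heap, (t2, i))
            continue

        dur = rng.gamma(
            config.visit_duration_shape,
            config.visit_duration_mean_s / config.visit_duration_shape,
        )
        dur = max(dur, 1.0)
        end = min(t + dur, T)
        if end <= t:
            continue
        busy_until[corner - 1] = end

        rewarded_here = phase.reward_map is not None and phase.reward_map.get(ids[i]) == corner
        access = phase.reward_map is None or rewarded_here
        sucrose = rewarded_here and phase.reward_liquid == "sucrose_10pct"

        # at least one poke per visit: a mouse enters a corner to sample the
        # bottle openings; visits without a single beam-break are rare
        n_pokes = 1 + int(rng.poisson(max(config.nosepoke_mean - 1.0, 0.0)))
        pokes: list[NosepokeEvent] = []
        if n_pokes > 0:
            times = np.sort(rng.uniform(t, end, size=n_pokes))
            for pt in times:
                door = bool(access)
                lick_mean = config.lick_mean * (
                    config.sucrose_lick_multiplier if sucrose else 1.0
                )
                licks = int(rng.poisson(lick_mean)) if door else 0
                pokes.append(
                    NosepokeEvent(
                        side="left" if rng.random() < 0.5 else "right",
                        time_s=float(pt),
                        duration_s=float(min(rng.exponential(2.0), end - pt)),
                        lick_count=licks,
                        lick_duration_s=licks * 0.08,
                        door_opened=door,
                    )
                )
        drank = any(pk.lick_count > 0 for pk in pokes)

        r = 1.0 if (rewarded_here and drank) else 0.0
        c = corner - 1
        V[i, c] += config.alpha * (r - V[i, c])
        H[i, c] += 1.0
        H[i] *= config.habit_decay

        raw_visits.append((t, end, corner, i, tuple(pokes)))

        t_next = next_arrival(end)
        if t_next is not None:
            heapq.heappush(heap, (t_next, i))

    raw_visits.sort(key=lambda rv: rv[0])
    visits = tuple(
        VisitEvent(vid, ids[i], corner, start, end, pokes)
        for vid, (start, end, corner, i, pokes) in enumerate(raw_visits)
    )
    return EventLog(tuple(animals), visits, (), config.t0_clock)


@dataclass(frozen=True)
class FearSimResult:
    """Traces per extinction session plus the two final tests.

    ``extinction_sessions[s][a]`` is animal ``a``'s trace on session
    ``s+1``; ``test_b`` is the final test in the extinction context,
    ``test_a`` the renewal test in the conditioning context.
    """

    extinction_sessions: list[list[FreezingTrace]]
    test_b: list[FreezingTrace]
    test_a: list[FreezingTrace]


def _place_bouts(
    schedule, p_target: float, rng: np.random.Generator, sample_rate_hz: float,
    window_s: float = 20.0, noise_sd: float = 0.08,
) -> np.ndarray:
    """Immobility trace realizing ~p_target freezing in each post-CS window.

    One contiguous bout per window, anchored at CS offset; bouts shorter
    than 1 s are dropped (they would not score as freezing anyway).
    """
    n = int(math.ceil(schedule.duration_s * sample_rate_hz))
    imm = np.zeros(n, dtype=bool)
    for cs in schedule.cs_events:
        f = float(np.clip(rng.normal(p_target, noise_sd), 0.0, 1.0))
        bout_s = f * window_s
        if bout_s < 1.0:
            continue
        i0 = int(round(cs.offset_s * sample_rate_hz))
        i1 = min(i0 + int(round(bout_s * sample_rate_hz)), n)
        imm[i0:i1] = True
    return imm


def simulate_freezing(
    n_animals: int,
    extinction_rate: float,
    renewal_gain: float = 1.0,
    seed: int = 0,
    n_sessions: int = 5,
    p0: float = 0.8,
    sample_rate_hz: float = 30.0,
) -> FearSimResult:
    """Synthetic freezing traces across extinction and renewal testing.

    Per-CS freezing probability decays geometrically across sessions,
    ``p_s = p0 * extinction_rate**(s-1)``; the renewal test in the
    conditioning context multiplies the post-extinction level by
    ``renewal_gain`` (clipped to 1).
    """
    if not 0 <= extinction_rate <= 1:
        raise ValueError("extinction_rate must be in [0, 1]")
    if renewal_gain < 0:
        raise ValueError("renewal_gain must be >= 0")
    if not 0 <= p0 <= 1:
        raise ValueError("p0 must be in [0, 1]")
    rng = np.random.default_rng(seed)
    ext_schedule = build_fear_schedule("extinction")
    test_schedule = build_fear_schedule("test")

    sessions: list[list[FreezingTrace]] = []
    for s in range(1, n_sessions + 1):
        p_s = p0 * extinction_rate ** (s - 1)
        sessions.append(
            [
                FreezingTrace(
                    f"m{a:02d}", sample_rate_hz,
                    _place_bouts(ext_schedule, p_s, rng, sample_rate_hz),
                    ext_schedule,
                )
                for a in range(n_animals)
            ]
        )
    p_final = p0 * extinction_rate**n_sessions
    test_b = [
        FreezingTrace(
            f"m{a:02d}", sample_rate_hz,
            _place_bouts(test_schedule, p_final, rng, sample_rate_hz),
            test_schedule,
        )
        for a in range(n_animals)
    ]
    p_renewal = min(1.0, p_final * renewal_gain)
    test_a = [
        FreezingTrace(
            f"m{a:02d}", sample_rate_hz,
            _place_bouts(test_schedule, p_renewal, rng, sample_rate_hz),
            test_schedule,
        )
        for a in range(n_animals)
    ]
    return FearSimResult(sessions, test_b, test_a)


def inject_corruption(
    log: EventLog, intervals: Sequence[ExclusionInterval]
) -> EventLog:
    """Delete events inside ``intervals`` and insert bracketing fault flags.

    The test harness for screening: after injection,
    :func:`~cagewalk.screening.detect_corruption` recovers the intervals
    (exactly, after bin snapping).
    """
    visits = tuple(
        v
        for v in log.visits
        if not any(iv.contains(v.start_s) for iv in intervals)
    )
    flags = list(log.flags)
    for iv in intervals:
        flags.append(HardwareFlag(iv.start_s, "controller", "fault_start"))
        flags.append(HardwareFlag(iv.end_s, "controller", "fault_end"))
    flags.sort(key=lambda f: f.time_s)
    return EventLog(log.animals, visits, tuple(flags), log.t0_clock)
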