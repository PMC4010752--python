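import pytest

from cagewalk.events_io import (
    AnimalRecord,
    EventLog,
    NosepokeEvent,
    VisitEvent,
)
from cagewalk.simulator import SimConfig, default_cohort, simulate_cohort

SHORT_DAYS = {
    "simple_adaptation": 0.5,
    "nosepoke_adaptation": 0.5,
    "place_preference": 0.5,
    "reversal": 0.5,
}


def make_animals(n, cage_id="cage0"):
    return [
        AnimalRecord(f"m{i:02d}", f"tag{i:03d}", "control", "cohort0", cage_id)
        for i in range(n)
    ]


def make_visit(vid, aid, corner, start, end, pokes=()):
    return VisitEvent(vid, aid, corner, start, end, tuple(pokes))


def make_poke(time_s, licks=0, door=False, side="left"):
    return NosepokeEvent(
        side=side,
        time_s=time_s,
        duration_s=1.0,
        lick_count=licks,
        lick_duration_s=0.08 * licks,
        door_opened=door,
    )


@pytest.fixture
def tiny_log():
    """Two animals, three hand-placed visits."""
    animals = make_animals(2)
    visits = (
        make_visit(0, "m00", 1, 10.0, 30.0, [make_poke(15.0, licks=3, door=True)]),
        make_visit(1, "m01", 2, 40.0, 55.0),
        make_visit(2, "m00", 3, 60.0, 70.0, [make_poke(61.0)]),
    )
    return EventLog(tuple(animals), visits, (), "12:00")


@pytest.fixture(scope="session")
def short_sim():
    """A 12-animal cohort over a compressed 2-day protocol (0.5 d per phase)."""
    cfg = SimConfig(n_animals=12, seed=7)
    animals, sched = default_cohort(cfg, {"durations_days": SHORT_DAYS})
    log = simulate_cohort(cfg, sched)
    return cfg, sched, log


@pytest.fixture(scope="session")
def default_sim():
    """A small cohort over the full default 13-day protocol."""
    cfg = SimConfig(n_animals=8, seed=11)
    animals, sched = default_cohort(cfg)
    log = simulate_cohort(cfg, sched)
    return cfg, sched, log
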