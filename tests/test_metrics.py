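import numpy as np
import pandas as pd
import pytest

from cagewalk.events_io import EventLog
from cagewalk.metrics import (
    BinGrid,
    activity_summary,
    bin_events,
    corner_distribution,
    grid_for_phase,
    lick_preference,
    pct_correct,
    pct_perseverative,
    visit_durations,
)
from cagewalk.protocol import build_schedule
from cagewalk.screening import ExclusionInterval
from conftest import make_animals, make_poke, make_visit

H = 3600.0


def _single_animal_log(visits_by_corner, bin_start=0.0, t0="13:00"):
    """n visits per corner for one animal, spaced 60 s apart from bin_start."""
    visits = []
    t = bin_start + 1.0
    vid = 0
    for corner, n in visits_by_corner.items():
        for _ in range(n):
            visits.append(make_visit(vid, "m00", corner, t, t + 30.0))
            vid += 1
            t += 60.0
    visits.sort(key=lambda v: v.start_s)
    return EventLog(tuple(make_animals(1)), tuple(visits), (), t0)


def test_event_binned_by_start_time():
    """A visit straddling a bin boundary counts once, in its start bin."""
    grid = BinGrid(43200.0, 0.0, 2)
    log = EventLog(
        tuple(make_animals(1)),
        (
            make_visit(0, "m00", 1, H, H + 30),
            make_visit(1, "m00", 2, 43199.5, 43201.0),
        ),
        (),
        "13:00",
    )
    counts = bin_events(log, grid)
    totals = counts.totals("visits")
    assert totals.at["m00", 0] == 2
    assert totals.at["m00", 1] == 0


def test_binning_conserves_counts_under_exclusion(short_sim):
    _, sched, log = short_sim
    grid = grid_for_phase(sched, log.t0_clock)
    ivs = [ExclusionInterval(12 * H, 24 * H, "manual")]
    counts = bin_events(log, grid, ivs, sched)
    kept = counts.totals("visits").to_numpy().sum()
    assert kept + counts.dropped == len(log.visits)
    assert counts.excluded_bins == {1}
    # licks and nosepokes conserved when nothing is excluded
    c0 = bin_events(log, grid, [], sched)
    assert c0.totals("licks").to_numpy().sum() == sum(
        p.lick_count for v in log.visits for p in v.nosepokes
    )
    assert c0.totals("nosepokes").to_numpy().sum() == sum(
        len(v.nosepokes) for v in log.visits
    )


def test_pct_correct_forced_arithmetic():
    log = _single_animal_log({1: 6, 2: 2, 3: 1, 4: 1})
    counts = bin_events(log, BinGrid(43200.0, 0.0, 1))
    t = pct_correct(counts, {"m00": 1})
    assert t["value"].iloc[0] == pytest.approx(60.0)
    t_all = pct_correct(bin_events(_single_animal_log({2: 5}), BinGrid(43200.0, 0.0, 1)), {"m00": 2})
    assert t_all["value"].iloc[0] == pytest.approx(100.0)


def test_pct_correct_missing_when_no_events():
    log = _single_animal_log({1: 3})
    counts = bin_events(log, BinGrid(43200.0, 0.0, 2))  # bin 1 empty
    t = pct_correct(counts, {"m00": 1})
    assert np.isnan(t[t.bin_index == 1]["value"].iloc[0])


def test_excluded_bin_yields_missing_not_zero():
    log = _single_animal_log({1: 4})
    counts = bin_events(
        log, BinGrid(43200.0, 0.0, 1), [ExclusionInterval(0.0, 43200.0)]
    )
    t = pct_correct(counts, {"m00": 1})
    assert np.isnan(t["value"]).all()


def test_perseveration_partition(short_sim):
    """correct% + perseverative% + other-two-corner% = 100 in reversal bins."""
    _, sched, log = short_sim
    grid = grid_for_phase(sched, log.t0_clock, "reversal")
    counts = bin_events(log, grid, schedule=sched, phase="reversal")
    prev = sched.phase("place_preference").reward_map
    now = sched.phase("reversal").reward_map
    pc = pct_correct(counts, now)["value"]
    pp = pct_perseverative(counts, prev)["value"]
    other = {
        aid: next(c for c in (1, 2, 3, 4) if c not in (prev[aid], now[aid]))
        for aid in prev
    }
    other2 = {
        aid: next(
            c for c in (4, 3, 2, 1) if c not in (prev[aid], now[aid], other[aid])
        )
        for aid in prev
    }
    po = pct_correct(counts, other)["value"] + pct_correct(counts, other2)["value"]
    total = pc + pp + po
    assert np.allclose(total.dropna(), 100.0)


def test_perseveration_requires_reversal_phase(short_sim):
    _, sched, log = short_sim
    grid = grid_for_phase(sched, log.t0_clock, "place_preference")
    counts = bin_events(log, grid, schedule=sched, phase="place_preference")
    with pytest.raises(ValueError, match="reversal"):
        pct_perseverative(counts, sched.phase("place_preference").reward_map)


def test_activity_summary_hand_arithmetic():
    """Group totals {10, 20, 30} -> mean 20, s.e.m. 10/sqrt(3)."""
    animals = make_animals(3)
    visits, vid, t = [], 0, 1.0
    for aid, n in (("m00", 10), ("m01", 20), ("m02", 30)):
        for _ in range(n):
            visits.append(make_visit(vid, aid, 1, t, t + 10.0))
            vid += 1
            t += 20.0
    log = EventLog(tuple(animals), tuple(visits), (), "13:00")
    counts = bin_events(log, BinGrid(43200.0, 0.0, 1))
    out = activity_summary(counts, {a.animal_id: "g" for a in animals})
    dark = out[out.ld_label == "dark"].iloc[0]
    assert dark["mean"] == pytest.approx(20.0)
    assert dark["sem"] == pytest.approx(10.0 / np.sqrt(3))
    light = out[out.ld_label == "light"].iloc[0]
    assert light["mean"] == 0.0 and light["sem"] == 0.0


def test_activity_summary_single_animal_group():
    log = _single_animal_log({1: 5})
    counts = bin_events(log, BinGrid(43200.0, 0.0, 1))
    out = activity_summary(counts, {"m00": "solo"})
    assert out[out.ld_label == "dark"]["mean"].iloc[0] == 5.0
    assert np.isnan(out[out.ld_label == "dark"]["sem"].iloc[0])


def test_corner_distribution_hand_values():
    log = _single_animal_log({1: 4, 2: 3, 3: 2, 4: 1})
    counts = bin_events(log, BinGrid(43200.0, 0.0, 1))
    out = corner_distribution(counts)
    assert out["pct_visits"].tolist() == pytest.approx([40.0, 30.0, 20.0, 10.0])


def test_corner_distribution_sums_to_100(short_sim):
    _, sched, log = short_sim
    grid = grid_for_phase(sched, log.t0_clock, "simple_adaptation")
    counts = bin_events(log, grid, schedule=sched, phase="simple_adaptation")
    out = corner_distribution(counts)
    sums = out.groupby("animal_id")["pct_visits"].sum()
    assert np.allclose(sums.dropna(), 100.0)


def test_corner_distribution_empty_animal_missing():
    log = EventLog(tuple(make_animals(1)), (), (), "13:00")
    counts = bin_events(log, BinGrid(43200.0, 0.0, 1))
    out = corner_distribution(counts)
    assert out["pct_visits"].isna().all()


def test_lick_preference_hand_built():
    sched = build_schedule({n: 1.0 for n in (
        "simple_adaptation", "nosepoke_adaptation", "place_preference", "reversal")})
    visits = [
        make_visit(0, "m00", 1, 25 * H, 25 * H + 60, [make_poke(25 * H + 1, 100, True)]),
        make_visit(1, "m00", 1, 37 * H, 37 * H + 60, [make_poke(37 * H + 1, 50, True)]),
        make_visit(2, "m00", 1, 49 * H, 49 * H + 60, [make_poke(49 * H + 1, 400, True)]),
        make_visit(3, "m00", 1, 61 * H, 61 * H + 60, [make_poke(61 * H + 1, 200, True)]),
    ]
    log = EventLog(tuple(make_animals(1)), tuple(visits), (), "13:00")
    out = lick_preference(log, sched).set_index("ld_label")
    assert out.loc["dark", "water_licks"] == 100
    assert out.loc["dark", "sucrose_licks"] == 400
    assert out.loc["light", "water_licks"] == 50
    assert out.loc["light", "sucrose_licks"] == 200


def test_lick_preference_sucrose_preferred_in_simulation(short_sim):
    _, sched, log = short_sim
    out = lick_preference(log, sched)
    assert out["sucrose_licks"].median() > out["water_licks"].median()


def test_lick_preference_excluded_bin_missing(short_sim):
    _, sched, log = short_sim
    ph = sched.phase("place_preference")
    ivs = [ExclusionInterval(ph.start_s, ph.end_s, "manual")]
    out = lick_preference(log, sched, ivs)
    assert out["sucrose_licks"].isna().all()
    # the compressed 0.5-d adaptation phase only spans a light bin
    assert out[out.ld_label == "light"]["water_licks"].notna().all()


def test_time_translation_invariance():
    """Shifting the log and grid together leaves percentages unchanged."""
    from dataclasses import replace

    log = _single_animal_log({1: 6, 2: 2, 3: 1, 4: 1})
    delta = 7 * H
    shifted = EventLog(
        log.animals,
        tuple(
            replace(
                v,
                start_s=v.start_s + delta,
                end_s=v.end_s + delta,
                nosepokes=tuple(
                    replace(p, time_s=p.time_s + delta) for p in v.nosepokes
                ),
            )
            for v in log.visits
        ),
        log.flags,
        log.t0_clock,
    )
    t1 = pct_correct(bin_events(log, BinGrid(43200.0, 0.0, 1)), {"m00": 1})
    t2 = pct_correct(bin_events(shifted, BinGrid(43200.0, delta, 1)), {"m00": 1})
    assert t1["value"].tolist() == t2["value"].tolist()


def test_visit_durations_exported(short_sim):
    _, sched, log = short_sim
    grid = grid_for_phase(sched, log.t0_clock)
    counts = bin_events(log, grid, schedule=sched)
    out = visit_durations(counts)
    total = out["value"].sum()
    assert total == pytest.approx(sum(v.end_s - v.start_s for v in log.visits))


def test_grid_bins_align_with_light_dark(short_sim):
    _, sched, log = short_sim
    grid = grid_for_phase(sched, log.t0_clock)
    counts = bin_events(log, grid, schedule=sched)
    # t0 at dark onset: labels alternate starting dark
    assert counts.ld_labels[0] == "dark"
    assert all(a != b for a, b in zip(counts.ld_labels, counts.ld_labels[1:]))
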