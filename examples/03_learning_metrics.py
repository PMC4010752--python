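"""Place-preference learning, reversal, and perseveration curves.

Two cohorts are simulated: one with a perseverative habit component and
one without. Per-animal percent-correct and percent-perseverative values
are computed in 12-h light/dark bins and the cohorts are compared per
bin with the exact Mann-Whitney U test.
"""

import pandas as pd

from cagewalk import (
    SimConfig, bin_events, grid_for_phase, pct_correct, pct_perseverative,
    per_bin_comparison, simulate_cohort,
)
from cagewalk.simulator import default_cohort


def phase_table(config, metric):
    _, sched = default_cohort(config)
    log = simulate_cohort(config, sched)
    prev_map = sched.phase("place_preference").reward_map
    if metric == "acquisition":
        grid = grid_for_phase(sched, log.t0_clock, "place_preference")
        counts = bin_events(log, grid, schedule=sched, phase="place_preference")
        return pct_correct(counts, prev_map)
    grid = grid_for_phase(sched, log.t0_clock, "reversal")
    counts = bin_events(log, grid, schedule=sched, phase="reversal")
    return pct_perseverative(counts, prev_map)


rigid = SimConfig(n_animals=12, seed=1, habit_gain=0.1, group_label="rigid")
flexible = SimConfig(n_animals=12, seed=2, habit_gain=0.0, group_label="flexible")

for metric in ("acquisition", "perseveration"):
    ta = phase_table(rigid, metric).assign(animal_id=lambda d: "r_" + d.animal_id)
    tb = phase_table(flexible, metric).assign(animal_id=lambda d: "f_" + d.animal_id)
    merged = pd.concat([ta, tb], ignore_index=True)
    print(f"\n{metric}: cohort means per 12-h bin (light/dark)")
    summary = merged.assign(cohort=merged.animal_id.str[0]).groupby(
        ["bin_index", "ld_label", "cohort"])["value"].mean().unstack()
    print(summary.round(1).to_string())
    comps = per_bin_comparison(merged, ta.animal_id.unique(), tb.animal_id.unique())
    for c in comps:
        print(f"  bin {c.bin_index}: U={c.U:.0f} p={c.p_two_sided:.4f} {c.significance}")
# Expected pattern: the habit cohort acquires the rewarded corner at least
# as well as the flexible one (a habit aligned with reward never hurts),
# but keeps returning to the formerly rewarded corner early in reversal —
# elevated perseveration with intact learning.
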