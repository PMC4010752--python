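"""Detect and exclude a corrupted segment from an event log.

A 14-h controller outage is injected into a clean simulated log; the
screener finds it from the bracketing hardware flags and the cage-wide
silence, snaps it outward to whole 12-h analysis bins, and removes the
affected events so no downstream metric can see them.
"""

from cagewalk import (
    ExclusionInterval, SimConfig, apply_exclusions, detect_corruption,
    grid_for_phase, inject_corruption, simulate_cohort,
)
from cagewalk.simulator import default_cohort

config = SimConfig(n_animals=12, seed=7)
_, schedule = default_cohort(config)
log = simulate_cohort(config, schedule)

outage = ExclusionInterval(2.3 * 86400, 2.3 * 86400 + 14 * 3600, "flagged")
corrupted = inject_corruption(log, [outage])
print(f"injected outage [{outage.start_s/3600:.1f} h, {outage.end_s/3600:.1f} h); "
      f"{len(log.visits) - len(corrupted.visits)} events lost")

grid = grid_for_phase(schedule, log.t0_clock)  # 12-h bins over the protocol
found = detect_corruption(corrupted, gap_threshold_s=3600, snap_to_bins=grid)
for iv in found:
    print(f"detected: [{iv.start_s/3600:.0f} h, {iv.end_s/3600:.0f} h) ({iv.reason})")

screened, dropped = apply_exclusions(corrupted, found)
print(f"{dropped} further events inside the snapped bins dropped; "
      f"{len(screened.visits)} remain for analysis")
# The detected interval covers the whole 12-h bins touched by the outage:
# partially observed bins are dropped, never renormalized.
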