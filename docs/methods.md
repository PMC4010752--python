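# Methods

## Scope and data model

`cagewalk` analyzes event logs from automated group-housing cages with
four single-occupancy operant corners. The native instrument archive
format is proprietary and undocumented, so the package defines its own
plain CSV interchange dialect (one visits table, one nosepokes table
keyed by visit id, one flags table, one animals table, and an optional
key–value `meta.csv` holding the wall clock of t = 0). Visits are atomic
records; reconstructing them from raw antenna pings is out of scope. All
timestamps are seconds since experiment start (float) and every interval
in the package — visits, bins, exclusions, scoring windows — is half-open
`[start, end)`, which makes binning and snapping arithmetic unambiguous.

Whole-log invariants (unique animal ids, unique transponder tags per
cage, visit ordering, nosepoke containment, lick/door consistency, and
single occupancy per corner) are checked by `validate_log`, which reports
violations rather than raising, so a damaged file can be triaged.

## Screening

Hardware outages are detected two ways: explicit fault flags, paired
consecutively in time order into bracketed spans (a trailing unpaired
flag extends to the last event), and cage-wide silent gaps of at least
`gap_threshold_s` (default 1 h) — a healthy cage of a dozen mice is never
silent that long (at the default light-phase rate of 1.5 visits/h/animal,
the chance of a spontaneous 1-h silence in a 12-animal cage is e^-18 per
gap). Detected intervals are snapped *outward* to whole 12-h analysis
bins by default and the affected bins are reported as missing rather than
renormalized: a partially observed bin would bias percentage metrics in
proportion to how much of it survived, whereas a missing bin is simply
absent from group comparisons. Manual exclusion intervals can be supplied
through the same CSV format. A visit is inside an interval iff its start
time is.

## Binning and metrics

Analysis bins are 12 h wide by default (6 h supported) and anchored at
the light–dark transition at or before the start of the phase being
analyzed, so each default bin lies wholly within one light or dark phase.
Events are assigned to the bin containing their start time; visits
spanning a boundary are not split. Percentage metrics (`pct_correct`,
`pct_perseverative`, corner distributions) emit *missing*, never 0, when
the denominator is zero — an animal that never visited during a bin is
not "0% correct" — and missing values are dropped per bin in the
statistics layer. Per-corner percentages partition: correct + perseverative
+ the two remaining corners sum to 100 wherever defined.

Cumulative visit duration is computed and exported but excluded from the
default report; duration is a labile parameter, far less replicable
across cohorts than visit and nosepoke counts, and percentage measures
built on counts are preferred throughout.

The lick-preference control compares water intake (last dark and last
light bin of nosepoke adaptation, tap water everywhere) with sucrose
intake (first dark and first light bin of place preference). The activity
control reports group mean ± s.e.m. (sample sd / √n; missing for groups
of one) of per-animal visit totals split by light/dark.

## Statistics

Groups are compared per bin with the two-sided Mann–Whitney U test. U is
computed from rank sums with midranks for ties. For pooled n ≤ 16 the
p-value is exact: without ties, the classical count recurrence over all
C(n_a+n_b, n_a) label assignments (mathematically identical to full
enumeration); with ties, literal enumeration of label assignments over
the midranks. The exact two-sided p uses the doubling convention,
min(1, 2·min-tail) — exact two-sided definitions vary, so this is stated
explicitly. Larger samples use the normal approximation with tie
correction to the variance and a 0.5 continuity correction. The
worst-case deviation of that approximation from the exact doubled-tail p
at n_a = n_b = 8 is 0.0109 (it occurs at U = 24, verified by scanning all
65 attainable U values); the property test asserts this computed bound.
No multiple-testing correction is applied across bins by default,
matching per-bin star annotation practice; Holm step-down adjustment is
available but off by default. Stars: p < 0.05 (*), < 0.01 (**),
< 0.001 (***).

## Protocol representation

The default schedule is simple adaptation 5 d, nosepoke adaptation 2 d,
place preference 3 d, reversal 3 d — 13 days total, all durations
overridable; the nosepoke-adaptation default of 2 d is chosen so the
phases sum to the canonical 13-day total. Rewarded corners are assigned
by a seeded shuffle + round-robin, never exceeding 3 animals per corner
(12 animals fill all corners exactly). "Opposite corner" for reversal is
the diagonal corner (1↔3, 2↔4) under a numbering where corners 1 and 2
share a wall — the diagonal maximizes spatial displacement; the mapping
is a fixed-point-free involution and is configurable.

Fear-conditioning timelines: conditioning is a 3-min baseline then five
20-s tone CSs, each co-terminating with a 1-s footshock US, 60-s
intertrial intervals (offset-to-onset) and a 30-s tail; extinction is 12
tones without shock; the renewal test is 2 tones. The US–CS alignment
(co-termination) is the common delay-conditioning convention and is
configurable. Extinction and test sessions reuse the same 180-s baseline
default, a choice made for uniformity.

## Freezing scorer

The scorer starts from a boolean immobility series (e.g. 30 Hz); video
motion estimation is the recorder's job and out of scope. An observation
is freezing iff it lies in a maximal immobility run of ≥ 1 s (inclusive
threshold), which makes the scorer monotone in the bout threshold. Per-CS
scores are the percentage of freezing observations in a 20-s window
anchored at CS offset — the literal reading of scoring "following" the
tone — with onset anchoring available, since both interpretations appear
in practice. Percentages are robust to sample rate up to one sample of
discretization at window edges.

## Synthetic cohorts

The simulator is the package's ground-truth source. Each animal is an
agent on the real protocol clock:

- **Activity**: visits arrive by an inhomogeneous Poisson process
  (thinning algorithm, exact for the piecewise-constant rate), λ_dark = 6
  and λ_light = 1.5 visits/h — nocturnal activity with per-phase totals
  on the order of 10² visits per animal, comparable to published group
  means. The experiment clock starts at dark onset (t0 = 13:00 by
  default) so 12-h bins align with light/dark phases from t = 0.
- **Choice**: softmax over `(V_c + habit_gain·H_c)/τ` across the four
  corners.
- **Learning**: after each visit, the chosen corner's value follows
  `V_c ← V_c + α(r − V_c)`, with r = 1 iff the animal drank in its
  rewarded corner during a reward phase. α defaults to 0.02, putting
  acquisition on a multi-day timescale (near chance in the first 12-h
  bin, ~84% by day 3) as in real place-preference learning; τ = 0.35
  bounds asymptotic accuracy near 85–95%, a realistic ceiling.
- **Perseveration**: the habit trace increments on the chosen corner and
  decays by `habit_decay` (default 0.9) per visit; `habit_gain` scales
  its pull. This gives a "rigidity" axis separate from the "cognition"
  axis α, which the metrics must dissociate.
- **Mechanics**: each visit draws ≥ 1 nosepoke (1 + Poisson; a corner
  visit without a single beam-break is rare in practice, and guaranteed
  sampling makes reward delivery deterministic where access exists);
  licks are Poisson with a 4× multiplier when the bottle holds 10%
  sucrose; single occupancy is enforced by deferring a visit aimed at an
  occupied corner by ~N(10 s, 2 s) rather than discarding it, preserving
  per-animal rates. Output is bit-reproducible given the seed and always
  passes `validate_log`.

Two named regimes reproduce the qualitative phenotypes the metrics are
designed to separate. A *rigid* cohort (habit_gain = 0.1 vs 0) shows
strongly elevated perseveration over the first reversal day with
acquisition at least as good as controls — a habit aligned with reward
never hurts acquisition in this model, which is why "intact acquisition"
is checked as non-inferiority rather than equality. A *slow-learning*
cohort (α = 0.002 vs 0.02) shows a global acquisition deficit with
perseveration no higher than controls': having barely acquired the first
corner, it has nothing to perseverate on. Note the model's one-α symmetry
implies that *moderately* slow learners (α ≈ 0.005–0.01) do look
perseverative — they unlearn as slowly as they learn — so the
deficit-without-perseveration phenotype exists only near the chance-level
regime.

The freezing simulator realizes a target per-CS freezing probability
p_s = p₀·rate^(s−1) by placing one contiguous immobility bout per post-CS
window (Gaussian jitter, sd 0.08; bouts < 1 s dropped since they cannot
score); the renewal test multiplies the post-extinction level by
`renewal_gain`, clipped to 1.

### What the simulator does and does not emulate

It emulates circadian activity, reward-driven place learning, habitual
perseveration, sucrose preference, single-occupancy mechanics, and
corruption injection with bracketing fault flags. It does not model
locomotion, social interaction, bottle-side (left/right) preferences,
satiety, or any pharmacology; group labels are just simulator parameter
sets. Passing tests therefore demonstrate that the *pipeline* recovers
known generative structure from well-formed event streams — not that any
biological claim about real cohorts is reproduced.

## Problem sizes and numerics

Simulation-based tests use 12-animal cohorts; parameter-recovery checks
run 20 replicate pairs of full 13-day cohorts per contrast, screening
round trips use 50 two-day cohorts, and the type-I calibration uses 1000
null draws at n = 8 + 8 where the exact null distribution applies. The
exact-U recurrence is cached per (n_a, n_b); tie enumeration is bounded
by pooled n ≤ 16 (≤ 12 870 assignments). Degenerate inputs are defined
explicitly: identical pooled samples give p = 1, empty groups raise,
zero-denominator bins are missing, groups of one have no s.e.m., and
bins with fewer than two values per group are skipped in comparisons.

## Known limitations

The CSV dialect is a documented stand-in, not the instrument's native
schema. Corruption detection is cage-wide; per-corner outages are not
modeled. The delta-rule agent has a single learning rate for learning and
unlearning, so it cannot express independently slow extinction of place
preference. Freezing analysis starts from immobility booleans; the
upstream motion threshold of commercial video scorers is not reproduced.
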