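# Methods

## Data model and time conventions

All events are keyed to seconds since a *session epoch* recorded in
`schedule.tsv`; the nine phases are contiguous whole-day blocks (3, 3, 3, 6,
6, 3, 1, 1, 3 days — 29 in total).  Analysis windows are half-open 24-h
slices `[t₀+(k−1)·86400, t₀+k·86400)` anchored at each phase's start, not at
midnight: the controller program switches phases at arbitrary clock times,
so "day k of phase P" is defined by the program, and the half-open
convention gives every event exactly one window.  A visit — with all of its
nosepokes and licks — is attributed to the window containing its entry
time.  This single-attribution rule is what makes per-day counts sum exactly
to whole-phase counts, a conservation property the test suite checks on
random cohorts.  The lights-on period (06:00–20:00) is expressed as the
fixed offsets 21600–72000 s within each epoch-anchored day.

The store itself is an abstract relational object (five pandas frames plus
the schedule); tab-separated text is the canonical interchange format.
Writes are canonically sorted and use 17-significant-digit floats with
round-trip parsing, so `read(write(s)) == s` holds exactly and repeated
writes are byte-identical.  Validation enforces referential integrity,
corner range, per-animal visit non-overlap, event containment in the visit
interval, and containment in the scheduled span, and names the first
offending row.

## Controllers

Door policy is a pure function of (phase, event kind, corner match): always
open in free adaptation; open on entry in door adaptation; open on nosepoke
in nosepoke adaptation and retention; open on nosepoke in the animal's
assigned corner in place preference and reversal; open only on a correct
trial in SRT; never open during avoidance (no water in that phase).  The
airpuff fires on a *nosepoke* in the animal's punished corner — a visit
without a poke never triggers it.

The SRT machine is the two-interval classifier described in the README.
Two edge conventions matter:

* a premature poke terminates the trial outright (it does not restart the
  pre-cue delay), and any terminal outcome locks the machine until corner
  exit, so one visit produces at most one trial and later pokes in the same
  visit are outside-trial;
* a trial left unresolved when the animal exits early is classified
  incorrect: the LED timer runs regardless of the animal's presence, so the
  7-s cue simply times out.  This keeps *initiated = correct + premature +
  incorrect* an exact partition, verified exhaustively against an
  independent brute-force enumerator over all ≤3-poke sequences on a 0.5-s
  grid.

Poke timing boundaries: a poke strictly before cue onset (`t < t₀+2`) is
premature; `t₀+2 ≤ t ≤ t₀+9` is correct (reaction time measured from cue
onset, hence in `[0, 7]`).

**Corner assignment.**  Each animal receives a reward corner among its
*least-visited* adaptation corners, subject to at most four animals per
corner and a per-corner genotype difference of at most one.  The algorithm
is deterministic: animals in ascending id, corners in order of (prior visit
count, corner index), accepting the first corner whose choice leaves the
remaining animals placeable — placeability is decided by a small exact
dynamic program over per-corner genotype counts, so the greedy never strands
a feasible instance and falls back to a next-least-visited corner only when
forced.  The reversal corner is the diagonal opposite under clockwise 1–4
indexing, `c ↦ ((c+1) mod 4)+1`, an involution; the SRT corner is the
reversal corner and the avoidance (airpuff) corner is the SRT corner.  After
stochastic exclusions the genotype totals in a cage can make the ±1 balance
infeasible (e.g. 8 survivors of one genotype and 2 of the other); the
simulator then relaxes the imbalance bound in unit steps until an assignment
exists, while the library function itself stays strict and raises.

## The mouse agent

Each simulated animal is an independent agent with genotype-level
parameters; one seeded generator drives the whole cohort (animals in roster
order, events merged by time), so cohorts are byte-reproducible.

* **Visit process** — a two-level Poisson process, `visit_rate_dark` /
  `visit_rate_light` visits per hour (dark > light), sampled by thinning,
  with a novelty boost `(1 + 0.8·e^{−t/1 day})` that elevates first-day
  activity and then decays; visits never overlap (the next visit starts
  after the previous ends).  Visit durations are log-normal with a 20-s
  median — real duration distributions are unreported, and only ordering
  and containment matter to the metrics, so this is a stand-in.
* **Corner choice** — with probability `w_explore` the visit is exploratory
  (uniform corner); otherwise it is water-seeking and targets the
  highest-weight corner.  Preference weights over the four corners start
  uniform and are reinforced after every rewarded drink,
  `w_c ← w_c + α(1−w_c)` with renormalization.
* **Extinction** — a nosepoke at a corner where the controller will not open
  the door for this animal (wrong corner in the place phases, any corner in
  avoidance) decays that corner's weight by the factor `1 − 0.10`.  Without
  this operant-extinction term an agent whose adaptation-phase favorite is
  dry would keep returning to it indefinitely and never discover the
  assigned corner; with it, both genotypes show the across-day learning
  curves the place-preference and reversal metrics are designed to capture.
* **Drinking** — only when the door opens; bout size `1 + Poisson(μ−1)`
  licks at 0.15-s spacing.  The per-bout mean (25) is kept moderate so that
  a 29-day cohort log stays in the hundreds of thousands of rows; only lick
  presence and counts enter any metric.  A Bernoulli `p_drink_fail` draw
  marks an animal as never learning to drink: it emits visits but no licks,
  and the generator applies the live removal rule (7 h out after the first
  zero-lick day, excluded after the second), truncating its event stream.
* **SRT behavior** — per initiated trial: premature with probability
  `p_impulsive` (poke uniformly inside the 2-s delay); otherwise a cue
  response with probability `p_attend` at latency `Exponential(rt_scale)`
  truncated to the 7-s cue; otherwise the trial times out (the agent
  lingers past the 9-s span so the timeout is observable in the log).
* **Avoidance** — each airpuff received multiplies the punished corner's
  weight by `1 − β` (`avoid_learn`), so return probability decays
  geometrically in the number of puffs.

### Default parameters

Defaults live in `src/intellipheno/default_config.toml`, not in code.  The
cohort is 8 + 8 animals per cage (a cage holds at most 16).  The genotype
deltas encode the qualitative contrasts the battery is meant to detect —
TG: lower visit rates (reduced day-1 exploration), `w_explore` 0.35 vs 0.60
(corner entries dominated by water-seeking), `p_drink_fail` 0.43 vs 0.13
(so expected pass rates are 57% vs 87%), `p_attend` 0.55 vs 0.70 (the
attention deficit), `avoid_learn` 0.25 vs 0.50 (slower avoidance learning,
hence more working-memory errors).  Shared constants (α = 0.15, impulsivity
0.15, reaction-time scale 2 s, exploration poke/drink probabilities 0.5/0.2,
extinction 0.10) are identical across genotypes.

### What the simulator does and does not emulate

It reproduces the statistical structure the analysis assumes: circadian
two-level visit rates, reinforcement-driven corner preference, controller-
contingent drinking, trial-level SRT outcome mixtures, punishment-driven
avoidance, and protocol-consistent exclusions — with ground truth retained.
It does not model thirst homeostasis or body weight, social interaction or
learning-by-imitation, smooth circadian curves (two levels suffice for the
day-resolution metrics), attentional learning across SRT days (`p_attend`
is constant, so simulated SRT %correct has no day trend), or side (left /
right port) preferences.  Passing tests therefore certify the pipeline's
correctness on data with these properties, not the realism of any particular
mouse strain.

## Metrics

Percentages are 0–100.  Zero-denominator animal-days yield missing values,
never 0 — a 0 would fabricate a behavioral score — and are removed by
listwise deletion before any repeated-measures fit.  Place-phase
correctness counts *visits* by corner identity alone (doors need a poke to
open, but the score's denominators are visits).  SRT outcome percentages
are defined over initiated trials so that the three outcomes partition
100%; `%initiated` is over all corner visits of the day; one visit
contributes at most one initiated trial.  Reaction time averages within an
animal-day first (the metric table is per animal-day), so any later
across-animal mean weights animals, not trials.  Adaptation pass/fail uses
the two-consecutive-zero-lick-window rule over the nine adaptation days; a
licking day clears the strike.

Every metric is verified against an independent straight-line recount of
the raw event rows (including an independent trial classifier) on 100
simulated cohorts.

## Statistics

The mixed ANOVA uses the classical univariate split-plot decomposition.
With complete data after listwise deletion the five sums of squares are
mutually orthogonal even with unequal group sizes (cell counts are
proportional because every retained subject contributes every day), so the
decomposition is exact; this is checked against a direct cell-means oracle
to 1e-9 and against an independent mixed-ANOVA implementation.  Between-
factor type-I error is calibrated by simulation (2000 null replicates,
0.05 ± 0.01).

Mauchly's W is computed on the orthonormal-contrast covariance, pooled
within groups (error df N−g), with the standard two-term chi-square
expansion; with two within levels sphericity holds trivially (W = 1,
p = 1).  No sphericity correction is applied by default; the
Greenhouse–Geisser ε is computed and reported, and applied only on request
— the battery's gating convention is to report the uncorrected test unless
sphericity is violated.  Bonferroni per-day post hocs (adjusted p = min(1,
p·d)) are only licensed by a significant interaction; calling them without
one raises.  Pooled t from summaries reconstructs SDᵢ = SEMᵢ·√nᵢ and is
exactly consistent with the raw-sample variant.

Printed degrees of freedom in published reports of such designs are
occasionally inconsistent with the standard split-plot dfs (e.g. a 6-day
within factor reported with df1 = 1, suggesting a linear-trend contrast);
this package always reports the standard dfs and does not attempt to
reproduce nonstandard pairs.  SRT runs for 3 days here: with the 6-day
place-preference and reversal phases, only a 3-day SRT is consistent with
the 29-day battery total.

## Problem sizes and determinism

Default verification sizes: 100 simulated cohorts for the metric-recount
equivalence, 50 cohorts of 12 + 12 for parameter recovery (pass-rate
ordering and ≥80% detection of the 0.15 `p_attend` deficit via the genotype
main effect on SRT %correct), 2000 replicates for ANOVA calibration, and
exhaustive enumeration (2625 sequences) for the trial machine.  All
randomness flows through seeded numpy generators; `simulate → analyze →
stats` with a fixed seed is byte-reproducible, and the analysis stages never
read the simulator's ground truth.

## Known limitations

Listwise deletion discards animals with any missing day within a phase;
classical RM-ANOVA requires complete cases, and a mixed-effects model that
tolerates missingness is out of scope.  The Mauchly chi-square approximation
is anti-conservative at small N (its simulated type-I error runs slightly
above nominal at N = 30, as the test suite documents).  Left/right port
side is recorded but unused.  The morphometric comparisons (body and brain
weight) are supported through summary-statistics t-tests; the simulator does
not generate weights.
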