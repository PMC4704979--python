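# Methods

This note documents the models and procedures implemented in `wmtrain`,
the parameters that matter, the numerical choices, and what the simulated
responders do and do not establish about real patients.

## Exercise engines

All three paradigms are simulated-time engines: a stimulus stream is a
pure function of `(config, seed)` (numpy `default_rng`), a block's
duration is accounted as `stimuli × isi` seconds, and a missed answer is
the `MISSED` sentinel rather than a wall-clock timeout. The response
window is taken equal to the inter-stimulus interval; there is no
real-time loop anywhere in the package.

**Vs-WM.** Cells are drawn uniformly *without replacement* within one
sequence. Repeating a cell would make "touch the corresponding locations"
ambiguous on a touch interface, so a sequence can never exceed the grid
size; this is also why the standard (fixed-grid) ladder is bounded.
Scoring is order-sensitive and position-by-position with no partial
credit for a right cell at the wrong position.

**Op-NB.** Each of the two digits is uniform on the inclusive span
`[digit_lo, digit_hi] ⊆ [1, 9]`, independently; the scored answer at
position *j* is the sum of stimulus *j*, given while stimulus *j + N* is
on screen. Scored positions start at the (N+1)-th stimulus.

**D-NB.** Digit and cell are independently uniform on {1..4}. Answers are
(digit-button 1–4, cell-button 5–8) with buttons 5–8 mapping left-to-right
onto the 4 cells. A half-right answer (digit right, cell wrong, or vice
versa) counts as a single incorrect answer: the two touches form one
answer.

Every scorer conserves counts (`correct + incorrect + missed = scored`)
and recomputes the percentage exactly as `100·correct/scored`; this is
property-tested and checked against exhaustive enumeration oracles on
small blocks.

## The adaptive working load

Validity thresholds (percent correct): 100 for Vs-WM, 80 for Op-NB, 75
for D-NB. The staircase is 1-up / 3-consecutive-down: +1 level per valid
block; the invalid streak is a consecutive counter that resets on any
valid block and on a decrement; only the third consecutive invalid block
decrements (floor at level 1). The level changes by at most one per block
and a new record is spawned only when it changes.

Ladders vary the rate first, then the parameter:

| paradigm | rate steps (isi, s)          | then grows            | bound |
|----------|------------------------------|-----------------------|-------|
| Vs-WM    | 2.0, 1.75, 1.5, 1.25, 1.0    | sequence length +1    | level 11 on a 3×3 grid |
| Op-NB    | 4.5, 4.0, 3.5, 3.0           | N +1, stimuli (N+1)×5 | none  |
| D-NB     | 4.5, 4.0, 3.5, 3.0           | N +1, stimuli (N+1)×5 | none  |

The rate thresholds (1 s and 3 s) and the parameter-growth rules are
protocol constants; the starting rates and step sizes are design choices
(the protocol does not fix them) and are configurable. Starting records
are equal for all patients: 3×3 grid / 3 stimuli and N = 0, at the
slowest rate. Successive levels differ in exactly one *independent*
parameter — the n-back block length is derived from N and does not count
as a second change. The grid is held fixed during adaptation; an optional
`grow_grid` ladder variant enlarges it minimally when the sequence no
longer fits, making the Vs-WM ladder unbounded. Bounded ladders saturate
at their ceiling (a valid block at the top level keeps the level).

## Scheduler and adherence

The `takeuchi-8w` preset (named for the published training schedule the
protocol followed) is 8 weeks × 5 sessions/week = 40 sessions, one
30-minute session per day, ~10 minutes per exercise per day. Weeks are
ISO calendar weeks; the default simulation start date is a Monday so
program weeks and ISO weeks coincide and a 5-session week fills
Monday–Friday. Session eligibility enforces the daily and weekly quotas
and the program duration.

Adherence is `100 × completed / scheduled`, rounded half-up to an integer
percent. Arithmetic is exact (`Fraction`, with floats interpreted through
their decimal literal), so a cohort mean of 33.4 of 40 is 83.5% and
prints as 84, and fractional cohort means are first-class inputs. The
inclusion cut-off is the smallest count whose adherence meets the
configured fraction (32 of 40 at 80%).

## Datastore

Entities live in a single SQLite file with the three-section schema
(Patients; Exercises and Treatments — records plus assignments; Settings,
a single active row holding the USER/ADMIN flag). Foreign keys are
enforced, and an auto-generated record bound to one patient can never be
assigned to another. Raw logs are append-only TSV text (UTF-8, one header
line, ISO-8601 timestamps, config snapshot as canonical JSON, floats
serialised with `repr` so the reader reproduces them bit-exactly); the
reader reports malformed lines by number and keeps parsing. Reports are
regenerated from the raw log, never cached. Export bundles are plain
directories (entity JSON, logs, per-patient report TSVs) with a SHA-256
manifest; import verifies every checksum before loading anything.

## Simulated responders

A responder answers each scored position independently: correct with
probability `p_high` at or below its capacity level, decaying linearly
with `slope` per level above capacity down to `p_floor`; independently,
each answer is missed with probability `miss_rate`. The correct count per
block is therefore binomial with success probability
`(1 − miss_rate) · p(level)`, which gives a closed-form validity
probability per level (`scipy.stats.binom`).

Defaults — capacity 4, `p_high` 0.95, `p_floor` 0.05, slope 0.45,
`miss_rate` 0 — were chosen from the staircase's balance point: a 1-up /
3-consecutive-down rule equilibrates where `P(valid) ≈ 0.206`
(`(1−p)³ = ½`), so a steep collapse above capacity pins the stationary
level distribution to within about one level of capacity. Wrong answers
are drawn uniformly from the non-matching alphabet; they never influence
counts, only the log contents. Response draws use a seed stream decoupled
from the stimulus seed so the logged block seed replays the stimuli
exactly.

`run_program` executes a full course closed-loop and deterministically
from one integer seed: greedy scheduling on eligible days, per-exercise
blocks until the simulated daily budget is exhausted (at least one block
of each paradigm per session), staircase update and record spawning after
every block, raw logging throughout. The protocol preset produces ~7–9
thousand blocks per 8-week run in under a second.

### Validation against the exact Markov chain

The staircase with level-dependent validity probability `p(ℓ)` is a
finite Markov chain on states `(level 1..L, streak 0..2)` (reflecting
floor and ceiling). Its stationary distribution is solved directly
(least-squares on `π(P − I) = 0` with the normalisation row appended —
robust to the near-singular systems that arise when some `p(ℓ)` is
extreme). Closed-loop simulations are compared level-by-level to the
exact marginal using **batch-means** Monte-Carlo errors (batches of 100
blocks, 3 SD bands): the level series is strongly autocorrelated, so a
naive binomial standard error would be anti-conservative. Burn-in is the
first 10% of blocks. The modal stationary level recovers the responder's
capacity to ±1 across capacities 3–8.

## What the simulations do and do not show

The responder model establishes that the engines, staircase, scheduler
and datastore compose correctly and that the staircase converges where
theory says it should. It is deliberately not a cognitive model: answers
are exchangeable within a block (no learning, fatigue, serial-position or
lure effects, no reaction times), capacity is static over the 8 weeks,
and attendance is perfect unless histories are constructed otherwise.
Outcome statistics that depend on real humans — the questionnaire Likert
means and per-patient adherence spread — are therefore only checked for
their arithmetic (exact proportions, mean/SE with the sample (n−1)
standard deviation) and for statistical sanity on synthetic cohorts, not
reproduced.

## Numerical and degenerate-input choices

* Percent comparisons against thresholds are plain float `>=`; the only
  exact-boundary case that matters, 100% for Vs-WM, is exact in floating
  point because `100·n/n = 100.0`.
* Half-up rounding routes through `Fraction(str(x))` to avoid binary
  representation artefacts (83.5 must round up).
* The minimum correct count for validity is `ceil(threshold·n/100)` in
  exact rational arithmetic.
* Degenerate configs fail fast: sequences longer than the grid, `N`
  leaving no scorable position, empty response streams, levels below 1.
* A degenerate Op-NB digit span (lo = hi) leaves a single possible sum;
  the simulated wrong answer is then `sum + 1` (off the response keypad,
  but scoring only tests inequality).
* All seeds are 31-bit so logs and configs survive any integer layer.

## Problem sizes used in the test suite

Closed-loop validation uses 10,000 blocks (chain agreement), 2,000 blocks
per capacity for recovery, and 20,000 steps for the constant-probability
chain; generator uniformity uses 10,000 draws; the replay oracle
enumerates all 8,190 valid/invalid strings up to length 12; scorer
enumeration covers every response assignment on reduced alphabets (up to
289 combinations per stream). The full suite runs in roughly ten seconds
on one CPU.
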