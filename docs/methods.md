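# Methods

This note documents the models, conventions, and defaults implemented in
`blockmaze`, the reasoning behind choices the design left open, and what the
synthetic data can and cannot show.

## The block language and its interpreter

Programs are ASTs over 7 block kinds: three atomic movement commands
(`MoveForward`, `TurnLeft`, `TurnRight`), three orientation-relative path
sensors (`IfPathForward/Left/Right`), and `Repeat`. Sensors carry an
optional `Else` socket; counting the Else-variants of the three sensors
separately would give 10 distinct block shapes, but the package treats
`Else` as a socket of its conditional, never as a block of its own. Under
this convention the canonical left-wall follower

    Repeat [IfPathLeft{TurnLeft, MoveForward} Else{TurnRight}]

counts exactly 5 blocks. Keywords are case-insensitive; commas and
whitespace both separate statements; `[]` and `{}` are interchangeable
(each opener must be closed by its own kind). A program may carry an
implicit top-level `Repeat` (`default_repeat`), the convention for sampled
stimulus programs; text serialization stores only the body and the flag
travels out-of-band (in the JSON mirror it is explicit), so round-tripping
is exact in both formats.

Execution semantics:

- The agent starts on the start cell facing the start orientation; blocks
  run sequentially.
- `MoveForward` advances one cell if the cell ahead is path; otherwise the
  attempted move is recorded and the run halts with `wall-collision`.
- Turns always succeed. Sensors evaluate the adjacent cell in the
  orientation-relative direction and run the then- or else-body.
- Every move, turn, and sensor evaluation costs exactly one action. In the
  stimulus videos this package emulates, conditionals are animated like
  movements, so they are timed equally; the `Repeat` loop-back itself is
  instantaneous and costs nothing.
- The goal is checked immediately after every move (prompt termination,
  even mid-body), not only at iteration boundaries.
- Runs halt with one of four outcomes: `goal-reached` (the only success),
  `wall-collision`, `program-exhausted` (a non-looping body ran out), or
  `step-cap`.

The default step cap is 12·W·H actions. Rationale: a wall follower
traverses each corridor of a tree maze at most twice (2·W·H moves is already
generous), and interleaved sensing and turning at most triples the action
count; 12·W·H leaves a further factor-of-two margin. The cap is a parameter
everywhere.

**Cycle short-circuiting.** Programs are memoryless: the agent state
(position, orientation) fully determines the rest of a run on a fixed maze.
If the state at the start of a top-level loop iteration repeats, the run
provably loops forever and would end in `step-cap` with exactly `max_steps`
actions. With `detect_cycles=True` the interpreter returns that outcome and
action count without burning the remaining steps (flagging
`cycle_detected`, with the trace truncated at the detection point). This is
outcome- and count-exact, is property-tested against the plain path, and is
used for generalization estimation and pair search; trace-level analyses
use the plain path.

## Maze generation

Mazes are W×H binary grids (path/wall), 0-based x=column / y=row with y
growing downward; off-grid cells behave as wall. Random mazes use a
rooms-lattice randomized-Prim construction — rooms at all odd (x, y),
passages carved until the rooms form a spanning tree — so the raw maze's
path-adjacency graph is connected and acyclic (checked by the tree identity
`path cells − 1 = adjacent path-cell pairs`, and by an independent graph
oracle in the tests). W and H must therefore be odd and ≥ 5.

Loops are injected by flipping each *interior* wall cell to path
independently with probability `f`. Border cells are never flipped:
border corridors hug the frame and read as leaks outside the maze. Because
flips only add path, all originally connected cells stay connected; a
flipped cell with no path neighbour forms a small unreachable pocket, which
is harmless (the agent can never enter it) and accepted as part of the
distribution rather than special-cased away.

Start and goal are placed per maze: uniformly random path cells subject to
a minimum BFS distance, with the start orientation drawn uniformly from the
directions with open path ahead (uniform over all four if enclosed).

Defaults, used consistently by the acceptance script and tests: 9×9,
`f = 0.05`, minimum start–goal distance ⌈(W+H)/2⌉ = 9, everything seeded.
These sizes are the package's own calibration of "a maze you can watch an
agent solve in a short video"; under them the left-wall follower solves
≈ 93–94% of sampled mazes (failures come from injected loops, which a wall
follower cannot always escape).

## Metrics

- Action efficiency: `−|Run(p, m)|`, computed for failure runs too but
  carrying the run's success flag. The flag, not the metric layer, decides
  inclusion downstream: the analysis drops both-fail trials in the
  action-efficiency condition (a more efficient *failure* is not a better
  behavior) and keeps them in representation efficiency, whose metric does
  not depend on behavior.
- Representation efficiency: `−program_length` under inclusive counting
  (an implicit top-level Repeat counts as one block).
- Generalization: Monte-Carlo mean of `Solves` over a maze sample with
  binomial standard error √(ĝ(1−ĝ)/M). Default M = 1,000 (SE ≤ 1.6
  percentage points — enough to resolve the order-of-magnitude contrasts
  the stimulus design needs). Each sampled maze gets a fresh start/goal
  placement, so the estimate is over the full task distribution, not a
  fixed endpoint pair. An exact enumerator over all 2^(W·H−2) grids with
  pinned start/goal (guarded to W·H ≤ 16) serves as the oracle the
  Monte-Carlo path is verified against.

## Stimulus generation

Programs are sampled from a PCFG: statement lists continue with probability
0.5 (geometric length), block kinds are uniform over the six
movement/sensor kinds, sensors take an `Else` with probability 0.5, and
sensor bodies recurse one level by default. The sampler never emits an
inner `Repeat` (an inner Repeat exits only on goal, making any code after
it dead) and wraps every body in the default Repeat. Samples are rejected
above 8 blocks (wrapper excluded) and deduplicated by canonical
serialization.

Matched pairs place two sampled programs on one displayed maze:

| condition | equal | different |
|---|---|---|
| AE | block count; generalization within 0.02; same outcome | action count by ≥ 5 |
| RE | action count (exactly); generalization within 0.02; same outcome | block count by ≥ 2 |
| GEN | block count; action count (exactly) | generalization ratio ≥ 10×, both succeed |

"Equal action efficiency" means equal trace *length*, not identical traces:
the videos the paradigm equates are equal-duration, not frame-identical.
The margins (5 actions, 2 blocks, 10×, 0.02) are the package's reading of
"substantially different" and are all config-exposed. In the generalization
ratio a Monte-Carlo zero cannot be a denominator, so the smaller estimate
is floored at 1/M — conservative, since it only ever shrinks the ratio.
Generalization pairs are restricted to both-success at generation time:
both-fail pairs with a 10× solved-fraction gap essentially do not exist in
the search space, and requesting them yields zero pairs plus a warning.

The displayed-maze pool uses a shorter minimum start–goal distance
(default 4) than the generalization sample: displayed runs must fit a short
watchable video (tens of actions), and pairs of successful runs with
*identical* action counts are vanishingly rare on hard mazes. The
generalization estimates behind the pairing always use the default (hard)
distribution. Each program appears in at most one pair across the whole
set, mirroring designs where no rater sees the same program twice.

Trial assignment deals each participant a random subset of pairs such that
every pair's assignment count deviates from the mean by at most one
(card-dealing over concatenated shuffles, with count-preserving swap
repair), and randomizes left/right presentation per trial.

## Synthetic observers

An observer chooses the predicted program (the one its condition metric
favors) with probability

    lapse/2 + (1 − lapse) · σ(β · (w_ae·Δ̃ae + w_re·Δ̃re + w_gen·Δ̃gen))

where Δ̃ are metric differences (predicted minus other) divided by
per-metric standardizers — the pooled standard deviations of differences
across the stimulus set — so that weights for actions, blocks, and
fractions are on one scale. Three presets (weights w_ae, w_re, w_gen; all
with lapse 0.05):

- `behaviorist` (2.0, 0, 0): external performance only.
- `cognitivist` (2.0, 1.0, 0.6): all three dimensions.
- `solves` (0.3, 0.1, 0.6): the "choose the program that solves more
  mazes" instruction modeled as a weight change — the generalization weight
  matches the cognitivist's while the efficiency weights shrink, so the two
  groups differ in the efficiency conditions and agree in generalization.

These numbers are synthetic-data assumptions chosen once to produce the
qualitative between-group pattern; they are not estimates of human
parameters. Since β multiplies the weights, only the products β·w are
identifiable; the refitter (`recover_weights`) therefore fixes β = 1 and
lapse = 0 and fits the three coefficients by logistic maximum likelihood
(statsmodels), reporting Wald 95% intervals and flagging constant-choice or
separated data instead of fitting them.

Participant nuisance parameters exist solely to exercise the exclusion
filters: per-participant log-normal trial response times (median ≈ 23 s),
session overhead, a 5-question comprehension score with 5% per-question
error, and a 98% attention-check pass rate put roughly 5% of a default
population below one of the exclusion thresholds.

What the synthetic data does *not* emulate: any actual human strategy for
estimating generalization, learning or fatigue across trials, response-time
dependence on difficulty, or item-level random effects. Passing tests
therefore validate the machinery (metrics, stimulus constraints, filters,
exact tests, recovery) under a known choice process — they say nothing
about how people weigh these metrics.

## Statistical analysis

Exclusions remove whole participants: total session under 10 minutes,
median trial response time under 10 s, two or more of five comprehension
questions wrong, failed attention check, or any single response under 3 s.
The filter is idempotent and logs which rule fired per exclusion.

- Binomial tests against chance are exact and two-sided under the
  minimal-likelihood (minlike) convention: the p-value sums all outcomes no
  more likely than the observed one. The convention is documented here
  because two-sided exact tests are not unique.
- Proportion intervals are normal-approximation `μ ± z·√(μ(1−μ)/n)`,
  clipped to [0, 1]; boundary cases (k = 0 or n) are flagged degenerate.
- Bonferroni multiplicity is the number of summaries in the family — the
  condition × task cells for pooled summaries (m = 6 in the bundled
  design), the per-pair cells for trial-level summaries.
- Group contrasts are two-sided Fisher exact tests on the 2×2 task × choice
  table per condition.
- Cross-task consistency is the Spearman correlation of per-pair choice
  fractions, with an exact permutation p-value for n ≤ 8 points and the
  t-approximation above; both-fail pairs are omitted from the
  action-efficiency correlation and included in representation efficiency.
- `power_min_n` computes exact binomial power: the smallest n whose exact
  rejection region at level α has probability ≥ the target under the
  alternative. Note that a true proportion of .6 at n = 200 does **not**
  reach p < .001 under this standard computation (the minimum n for 95%
  power at α = .001 is 604); power claims of that shape evidently rest on a
  different calculation, and the package documents rather than reproduces
  them.

## Pipeline and reproducibility

`run_pipeline` chains stimulus generation, two simulated task groups, and
the analysis, writing every artifact (stimuli JSON, response and design
CSVs, summaries/contrasts/correlations, a plain-text report echoing the
full config) plus a manifest of SHA-256 content hashes. One master seed
derives all stage seeds through numpy's `SeedSequence` with the stage index
as spawn key, so stages can be rerun in isolation and identical configs are
byte-identical. The bundled default runs 20 pairs per condition over a
3,000-program pool and 60 displayed mazes, generalization at M = 300 during
search, and 2 × 200 participants × 15 trials — sizes chosen so the whole
pipeline completes in a few seconds while leaving every per-condition cell
with ~1,000 analyzable trials.

## Known limitations

- The wall-follower solve rate is a property of *this* maze distribution
  (9×9, f = 0.05); materially different sizes or loop fractions change it.
- Pair search yield depends on pool sizes; the generalization condition
  needs pairs of successful equal-length equal-duration runs, which exist
  only on the easier displayed-maze distribution.
- Monte-Carlo generalization with M = 300 during search has ~3-point SE per
  program; the near-equality tolerance (0.02) is therefore a tolerance on
  *estimates* under the fixed, seeded sample, which is also what the audit
  re-checks.
- The observer model is linear-in-metrics with a logistic link; it cannot
  express lexicographic or interactive strategies.
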