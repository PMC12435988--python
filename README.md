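# blockmaze

Tools for studying how observers evaluate *agents* versus the *algorithms*
that drive them, in a maze-navigation microworld. The package implements a
small Scratch-like block programming language whose programs steer an agent
through grid mazes, three program-evaluation metrics, an automatic generator
of matched two-alternative stimulus pairs, synthetic observers that stand in
for human raters, and the exact-test statistics of a two-alternative
forced-choice (2AFC) experiment.

It is aimed at computational cognitive scientists who want a fully seeded,
end-to-end testbed for "intuitive behaviorism vs. intuitive cognitivism"
designs: do observers rate an agent only by its outward behavior, or also by
properties of the program producing that behavior?

## The model

A program `p` is an AST over 7 block kinds — `MoveForward`, `TurnLeft`,
`TurnRight`, the sensors `IfPathForward/Left/Right` (each with an optional
`Else` socket), and `Repeat`, which re-runs its body until the agent reaches
the goal. Running `p` on a maze `m` yields the action trace `Run(p, m)`
(moves, turns, and sensor evaluations all cost one action) and the success
flag `Solves(p, m)`; walking into a wall halts the run immediately.

Three metrics score a program:

- **Action Efficiency** `AE(p, m) = −|Run(p, m)|` — negative action count of
  the observed run; a purely behavioral quantity.
- **Representation Efficiency** `RE(p) = −|p|` — negative block count of the
  code; a description-length quantity.
- **Generalization** `G(p) = (1/M) Σ_m Solves(p, m)` — the fraction of maze
  space the program solves. The space of W×H binary grids has 2^(W·H)
  members, so `G` is estimated by Monte Carlo over `M` mazes drawn from a
  rooms-lattice randomized-Prim generator (loop-free spanning trees) with a
  small fraction of interior wall cells flipped open to inject loops; tiny
  spaces (W·H ≤ 16) can be enumerated exactly.

Matched stimulus pairs put two programs on the same maze such that exactly
one metric differs substantially (the condition) while the other two are
equal — or nearly equal, for generalization — and both programs share the
same outcome. Synthetic observers then choose between the programs with
probability `lapse/2 + (1−lapse)·σ(β · w·Δ̃)`, where `Δ̃` are standardized
metric differences, and the analysis layer applies participant exclusion
filters, exact binomial tests against chance with Bonferroni correction,
normal-approximation proportion intervals, Fisher exact group contrasts, and
Spearman trial-level correlations.

## Worked example

The canonical left-wall follower keeps a hand on the left wall and therefore
fully explores any simply connected maze:

```python
from blockmaze import parse_program, program_length, sample_mazes, MazeGenParams
from blockmaze.metrics import evaluate_program

prog = parse_program("Repeat [IfPathLeft{TurnLeft, MoveForward} Else{TurnRight}]")
print(program_length(prog))            # 5  (Else is a socket, not a block)

sample = sample_mazes(MazeGenParams(seed=1), 1000)   # 9x9, loop fraction 0.05
print(evaluate_program(prog, sample.mazes[0], sample))
```

prints

```
5
MetricTriple(action_efficiency=-223, ae_success=True,
             representation_efficiency=-5,
             generalization=0.936, generalization_se=0.0077, M=1000)
```

Read: on the first sampled maze the follower reached the goal in 223 actions
(it explores exhaustively, so it is slow); its code costs 5 blocks; and it
solved 93.6% ± 0.8% of 1,000 sampled mazes — high generalization, mediocre
action efficiency, excellent representation efficiency.

The same things are available from a shell:

```bash
blockmaze gen-mazes --count 10 --seed 1 --out mazes/
blockmaze run --program wf.txt --maze mazes/maze_0000.txt --trace-out trace.csv
blockmaze metrics --program wf.txt --sample-size 1000 --seed 1
blockmaze pipeline --seed 0 --out report/
```

`blockmaze pipeline` runs the whole study design: it samples a program pool
from the PCFG, searches out 60 matched pairs (20 per condition), simulates
two task groups of 200 synthetic participants ("choose the better program"
vs. "choose the program that solves more mazes"), applies the exclusion
filters, and writes summaries, group contrasts, correlations, and a manifest
of content hashes — identical config and seed give byte-identical outputs.

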