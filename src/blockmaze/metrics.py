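"""The three program-evaluation metrics.

Action efficiency is the negative action count of a run (a purely behavioral
quantity); representation efficiency is the negative block count of the code
(a description-length quantity); generalization is the fraction of a maze
space the program solves, estimated by Monte Carlo over a maze sample or
computed exactly over a small enumerable space.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

from .blockdsl import Program, program_length
from .interpreter import run_program, default_step_cap
from .mazegen import Maze, MazeGenParams, MazeSample, enumerate_mazes, sample_mazes

__all__ = [
    "MetricTriple",
    "action_efficiency",
    "representation_efficiency",
    "generalization_mc",
    "generalization_exact",
    "evaluate_program",
    "DEFAULT_GENERALIZATION_M",
]

#: Default Monte-Carlo sample size; SE ≤ 1.6 percentage points, enough to
#: resolve order-of-magnitude generalization differences.
DEFAULT_GENERALIZATION_M = 1000


@dataclass(frozen=True)
class MetricTriple:
    action_efficiency: int  # -(run action count)
    ae_success: bool  # failure runs are flagged so analyses can drop them
    representation_efficiency: int  # -(inclusive block count)
    generalization: float
    generalization_se: float
    M: int  # Monte-Carlo sample size used


def action_efficiency(
    p: Program, m: Maze, max_steps: Optional[int] = None
) -> tuple[int, bool]:
    """−|Run(p, m)| with the run's success flag.

    The value is computed for failure runs too; the flag lets the analysis
    layer decide whether to keep them (failures are dropped in the
    action-efficiency condition but kept in representation efficiency, whose
    metric does not depend on behavior)."""
    res = run_program(p, m, max_steps, record_trace=False)
    return -res.n_actions, res.success


def representation_efficiency(p: Program) -> int:
    """Negative code length −|p| under inclusive block counting."""
    return -program_length(p, count_default_repeat=True)


def generalization_mc(
    p: Program,
    sample: MazeSample,
    max_steps: Optional[int] = None,
    *,
    detect_cycles: bool = True,
) -> tuple[float, float]:
    """Fraction of the maze sample solved, with its binomial standard error
    sqrt(g(1-g)/M)."""
    if sample.M < 1:
        raise ValueError("maze sample must be non-empty")
    solved = 0
    for m in sample.mazes:
        res = run_program(
            p, m, max_steps, record_trace=False, detect_cycles=detect_cycles
        )
        solved += res.success
    g = solved / sample.M
    se = math.sqrt(g * (1.0 - g) / sample.M)
    return g, se


def generalization_exact(
    p: Program,
    width: int,
    height: int,
    start: tuple[int, int],
    goal: tuple[int, int],
    start_orientation: str,
    max_steps: Optional[int] = None,
) -> float:
    """Exact solved fraction over the full 2^(W·H−2) grid enumeration with
    fixed start/goal.  Guarded to W·H ≤ 16."""
    total = 0
    solved = 0
    for m in enumerate_mazes(width, height, start, goal, start_orientation):
        total += 1
        res = run_program(p, m, max_steps, record_trace=False, detect_cycles=True)
        solved += res.success
    return solved / total


def evaluate_program(
    p: Program,
    m: Maze,
    sample: MazeSample,
    max_steps: Optional[int] = None,
) -> MetricTriple:
    """All three metrics of ``p``, with the run evaluated on ``m`` and
    generalization estimated over ``sample``."""
    ae, ok = action_efficiency(p, m, max_steps)
    g, se = generalization_mc(p, sample, max_steps)
    return MetricTriple(
        action_efficiency=ae,
        ae_success=ok,
        representation_efficiency=representation_efficiency(p),
        generalization=g,
        generalization_se=se,
        M=sample.M,
    )
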