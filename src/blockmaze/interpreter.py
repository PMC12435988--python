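"""Program execution on mazes.

Semantics: the agent starts at the maze's start cell facing its start
orientation; blocks execute sequentially.  MoveForward advances one cell if
the cell ahead is path, otherwise the attempted move is recorded and the run
halts with a wall collision.  Turns always succeed.  Conditionals evaluate
the adjacent cell in the orientation-relative direction (one sense action
carrying the truth value) and run their then- or else-body.  Repeat re-runs
its body until the agent reaches the goal.  The goal is checked immediately
after every move.  Every move, turn, and sense evaluation costs one action
(conditionals are animated like movements in the stimuli, so they are timed
equally); the Repeat loop-back itself is free.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .blockdsl import Block, BlockKind, Program
from .mazegen import Maze

__all__ = [
    "AgentState",
    "Action",
    "Trace",
    "RunResult",
    "run_program",
    "GOAL_REACHED",
    "WALL_COLLISION",
    "PROGRAM_EXHAUSTED",
    "STEP_CAP",
    "default_step_cap",
]

GOAL_REACHED = "goal-reached"
WALL_COLLISION = "wall-collision"
PROGRAM_EXHAUSTED = "program-exhausted"
STEP_CAP = "step-cap"

_DELTAS = {"N": (0, -1), "E": (1, 0), "S": (0, 1), "W": (-1, 0)}
_LEFT = {"N": "W", "W": "S", "S": "E", "E": "N"}
_RIGHT = {v: k for k, v in _LEFT.items()}

_SENSE_KIND = {
    BlockKind.IF_PATH_FORWARD: "sense-forward",
    BlockKind.IF_PATH_LEFT: "sense-left",
    BlockKind.IF_PATH_RIGHT: "sense-right",
}


@dataclass(frozen=True)
class AgentState:
    x: int
    y: int
    orientation: str


@dataclass(frozen=True)
class Action:
    kind: str  # move | turn-left | turn-right | sense-forward | sense-left | sense-right
    sensed: Optional[bool] = None


@dataclass
class Trace:
    actions: list[Action] = field(default_factory=list)
    states: list[AgentState] = field(default_factory=list)  # post-action states


@dataclass
class RunResult:
    trace: Trace
    outcome: str
    n_actions: int
    cycle_detected: bool = False

    @property
    def success(self) -> bool:
        return self.outcome == GOAL_REACHED


class _Halt(Exception):
    def __init__(self, outcome: str):
        self.outcome = outcome


def default_step_cap(maze: Maze) -> int:
    """12·W·H: a wall follower traverses each corridor at most twice and
    sensing/turning at most triples the action count, so this bound is safe."""
    return 12 * maze.width * maze.height


def run_program(
    program: Program,
    maze: Maze,
    max_steps: Optional[int] = None,
    *,
    record_trace: bool = True,
    detect_cycles: bool = False,
) -> RunResult:
    """Execute ``program`` on ``maze`` and return the action trace and outcome.

    All runtime failures are outcomes (wall-collision, program-exhausted,
    step-cap), never exceptions.  With ``detect_cycles=True``, a repeated
    agent state at a top-level loop boundary — which, for these memoryless
    programs on a fixed maze, proves the run would repeat forever and end in
    step-cap with exactly ``max_steps`` actions — short-circuits the run; the
    result then reports ``n_actions == max_steps`` with a truncated trace and
    ``cycle_detected=True``.
    """
    if maze.start is None or maze.goal is None or maze.start_orientation is None:
        raise ValueError("maze must carry start, orientation, and goal")
    if max_steps is None:
        max_steps = default_step_cap(maze)
    if max_steps < 1:
        raise ValueError("max_steps must be >= 1")

    rows = maze.grid.tolist()
    width, height = maze.width, maze.height
    gx, gy = maze.goal
    x, y = maze.start
    d = maze.start_orientation

    actions: list[Action] = []
    states: list[AgentState] = []
    count = 0

    def is_path(cx: int, cy: int) -> bool:
        return 0 <= cx < width and 0 <= cy < height and rows[cy][cx]

    def record(kind: str, sensed: Optional[bool] = None) -> None:
        nonlocal count
        count += 1
        if record_trace:
            actions.append(Action(kind, sensed))
            states.append(AgentState(x, y, d))

    def check_cap() -> None:
        if count >= max_steps:
            raise _Halt(STEP_CAP)

    def do_block(b: Block) -> None:
        nonlocal x, y, d
        k = b.kind
        if k is BlockKind.MOVE_FORWARD:
            check_cap()
            dx, dy = _DELTAS[d]
            nx, ny = x + dx, y + dy
            if is_path(nx, ny):
                x, y = nx, ny
                record("move")
                if x == gx and y == gy:
                    raise _Halt(GOAL_REACHED)
            else:
                record("move")
                raise _Halt(WALL_COLLISION)
        elif k is BlockKind.TURN_LEFT:
            check_cap()
            d = _LEFT[d]
            record("turn-left")
        elif k is BlockKind.TURN_RIGHT:
            check_cap()
            d = _RIGHT[d]
            record("turn-right")
        elif k is BlockKind.REPEAT:
            while True:
                for sub in b.then_body:
                    do_block(sub)
        else:  # conditional
            check_cap()
            if k is BlockKind.IF_PATH_FORWARD:
                sd = d
            elif k is BlockKind.IF_PATH_LEFT:
                sd = _LEFT[d]
            else:
                sd = _RIGHT[d]
            dx, dy = _DELTAS[sd]
            sensed = is_path(x + dx, y + dy)
            record(_SENSE_KIND[k], sensed)
            branch = b.then_body if sensed else b.else_body
            if branch:
                for sub in branch:
                    do_block(sub)

    cycle_detected = False
    try:
        body = program.body
        if program.default_repeat or (
            len(body) == 1 and body[0].kind is BlockKind.REPEAT
        ):
            loop_body = body if program.default_repeat else body[0].then_body
            seen: set[tuple[int, int, str]] = set()
            while True:
                if detect_cycles:
                    state = (x, y, d)
                    if state in seen:
                        cycle_detected = True
                        raise _Halt(STEP_CAP)
                    seen.add(state)
                for b in loop_body:
                    do_block(b)
        else:
            for b in body:
                do_block(b)
            raise _Halt(PROGRAM_EXHAUSTED)
    except _Halt as halt:
        outcome = halt.outcome

    n_actions = max_steps if cycle_detected else count
    return RunResult(
        Trace(actions, states), outcome, n_actions, cycle_detected=cycle_detected
    )
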