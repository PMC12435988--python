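"""Independent reference interpreter used as an equivalence oracle.

Deliberately written in a different style from the package's interpreter: an
iterative stack machine over explicit frames instead of a recursive tree
walker, with its own direction arithmetic.  Shares nothing with
blockmaze.interpreter except the AST/maze types.
"""

from blockmaze.blockdsl import BlockKind

# directions as indices 0..3 = N E S W; turning is modular arithmetic
_DIRS = "NESW"
_DX = [0, 1, 0, -1]
_DY = [-1, 0, 1, 0]

_SENSE_NAME = {
    BlockKind.IF_PATH_FORWARD: ("sense-forward", 0),
    BlockKind.IF_PATH_LEFT: ("sense-left", -1),
    BlockKind.IF_PATH_RIGHT: ("sense-right", 1),
}


def reference_run(program, maze, max_steps):
    """Return (outcome, actions, states) where actions is a list of
    (kind, sensed) tuples and states a list of (x, y, orientation) after
    each action."""
    grid = maze.grid
    w, h = maze.width, maze.height
    gx, gy = maze.goal
    x, y = maze.start
    d = _DIRS.index(maze.start_orientation)

    actions = []
    states = []
    outcome = None

    def open_at(cx, cy):
        return 0 <= cx < w and 0 <= cy < h and bool(grid[cy, cx])

    # frames: [blocks, next_index, is_loop]
    frames = [[list(program.body), 0, bool(program.default_repeat)]]

    while outcome is None:
        if not frames:
            outcome = "program-exhausted"
            break
        top = frames[-1]
        blocks, idx, looping = top
        if idx >= len(blocks):
            if looping:
                top[1] = 0
            else:
                frames.pop()
            continue
        top[1] = idx + 1
        b = blocks[idx]
        kind = b.kind

        if kind is BlockKind.REPEAT:
            frames.append([list(b.then_body), 0, True])
            continue

        # every remaining kind emits exactly one action
        if len(actions) >= max_steps:
            outcome = "step-cap"
            break

        if kind is BlockKind.MOVE_FORWARD:
            nx, ny = x + _DX[d], y + _DY[d]
            if open_at(nx, ny):
                x, y = nx, ny
                actions.append(("move", None))
                states.append((x, y, _DIRS[d]))
                if (x, y) == (gx, gy):
                    outcome = "goal-reached"
            else:
                actions.append(("move", None))
                states.append((x, y, _DIRS[d]))
                outcome = "wall-collision"
        elif kind is BlockKind.TURN_LEFT:
            d = (d - 1) % 4
            actions.append(("turn-left", None))
            states.append((x, y, _DIRS[d]))
        elif kind is BlockKind.TURN_RIGHT:
            d = (d + 1) % 4
            actions.append(("turn-right", None))
            states.append((x, y, _DIRS[d]))
        else:
            name, turn = _SENSE_NAME[kind]
            sd = (d + turn) % 4
            sensed = open_at(x + _DX[sd], y + _DY[sd])
            actions.append((name, sensed))
            states.append((x, y, _DIRS[d]))
            branch = b.then_body if sensed else b.else_body
            if branch:
                frames.append([list(branch), 0, False])

    return outcome, actions, states
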