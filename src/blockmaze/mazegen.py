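"""Maze generation and I/O.

Mazes are W×H binary grids (True = path) with a start cell, a start
orientation (compass letter), and a goal cell.  Coordinates are 0-based
(x = column, y = row, y grows downward); anything outside the grid behaves
as wall.

Random mazes use a rooms-lattice randomized-Prim construction: rooms sit at
all odd (x, y) coordinates and passages are carved between adjacent rooms
until they form a spanning tree, so the raw maze is loop-free.  Loops are
then injected by flipping a small fraction of interior wall cells to path.
"""

from __future__ import annotations

import itertools
import math
from collections import deque
from dataclasses import dataclass, field, replace
from typing import Iterator, Optional

import numpy as np

__all__ = [
    "Maze",
    "MazeGenParams",
    "MazeSample",
    "PlacementError",
    "generate_prim_maze",
    "add_loops",
    "place_start_goal",
    "enumerate_mazes",
    "shortest_path_steps",
    "sample_mazes",
    "maze_to_text",
    "maze_from_text",
    "DIRECTIONS",
]

DIRECTIONS = ("N", "E", "S", "W")
_DELTAS = {"N": (0, -1), "E": (1, 0), "S": (0, 1), "W": (-1, 0)}


class PlacementError(RuntimeError):
    """No start/goal placement satisfies the distance constraint."""


@dataclass(eq=False)
class Maze:
    grid: np.ndarray  # shape (H, W), dtype bool, True = path
    start: Optional[tuple[int, int]] = None
    start_orientation: Optional[str] = None
    goal: Optional[tuple[int, int]] = None

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=bool)
        if self.grid.ndim != 2:
            raise ValueError("grid must be 2-D")
        if self.start_orientation is not None and self.start_orientation not in DIRECTIONS:
            raise ValueError(f"bad orientation {self.start_orientation!r}")
        for name in ("start", "goal"):
            cell = getattr(self, name)
            if cell is not None and not self.is_path(*cell):
                raise ValueError(f"{name} {cell} is not a path cell")
        if self.start is not None and self.start == self.goal:
            raise ValueError("start and goal must differ")

    @property
    def width(self) -> int:
        return self.grid.shape[1]

    @property
    def height(self) -> int:
        return self.grid.shape[0]

    def is_path(self, x: int, y: int) -> bool:
        return 0 <= x < self.width and 0 <= y < self.height and bool(self.grid[y, x])

    def path_cells(self) -> list[tuple[int, int]]:
        ys, xs = np.nonzero(self.grid)
        return [(int(x), int(y)) for x, y in zip(xs, ys)]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Maze):
            return NotImplemented
        return (
            self.grid.shape == other.grid.shape
            and bool(np.array_equal(self.grid, other.grid))
            and self.start == other.start
            and self.goal == other.goal
            and self.start_orientation == other.start_orientation
        )


@dataclass(frozen=True)
class MazeGenParams:
    """Parameters of the random maze distribution.

    width/height must be odd and ≥ 5 (rooms-lattice convention);
    loop_fraction is the per-cell flip probability of interior wall cells;
    min_start_goal_distance defaults to ceil((W + H) / 2)."""

    width: int = 9
    height: int = 9
    loop_fraction: float = 0.05
    min_start_goal_distance: Optional[int] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width % 2 == 0 or self.height % 2 == 0:
            raise ValueError("width and height must be odd")
        if self.width < 5 or self.height < 5:
            raise ValueError("width and height must be >= 5")
        if not 0.0 <= self.loop_fraction <= 1.0:
            raise ValueError("loop_fraction must be in [0, 1]")

    @property
    def effective_min_dist(self) -> int:
        if self.min_start_goal_distance is not None:
            return self.min_start_goal_distance
        return math.ceil((self.width + self.height) / 2)


@dataclass
class MazeSample:
    mazes: list[Maze]
    params: MazeGenParams

    @property
    def M(self) -> int:
        return len(self.mazes)


def generate_prim_maze(params: MazeGenParams) -> Maze:
    """Loop-free randomized-Prim maze (no start/goal placed yet).

    Rooms at all odd (x, y) become path; passages between adjacent rooms are
    carved by randomized Prim until the rooms form a spanning tree, so the
    path-cell adjacency graph is connected and acyclic."""
    rng = np.random.default_rng(params.seed)
    return _prim_grid(params.width, params.height, rng)


def _prim_grid(width: int, height: int, rng: np.random.Generator) -> Maze:
    grid = np.zeros((height, width), dtype=bool)
    rooms = [(x, y) for y in range(1, height, 2) for x in range(1, width, 2)]
    start_room = rooms[int(rng.integers(len(rooms)))]
    grid[start_room[1], start_room[0]] = True
    in_tree = {start_room}
    frontier: list[tuple[tuple[int, int], tuple[int, int], tuple[int, int]]] = []

    def push_walls(room: tuple[int, int]) -> None:
        x, y = room
        for dx, dy in ((0, -2), (2, 0), (0, 2), (-2, 0)):
            nx, ny = x + dx, y + dy
            if 0 < nx < width and 0 < ny < height:
                frontier.append(((x, y), (nx, ny), (x + dx // 2, y + dy // 2)))

    push_walls(start_room)
    while frontier:
        idx = int(rng.integers(len(frontier)))
        _, nbr, passage = frontier.pop(idx)
        if nbr in in_tree:
            continue
        grid[passage[1], passage[0]] = True
        grid[nbr[1], nbr[0]] = True
        in_tree.add(nbr)
        push_walls(nbr)
    return Maze(grid)


def add_loops(maze: Maze, f: float, seed: int) -> Maze:
    """Flip each interior wall cell to path independently with probability f.

    The resulting path set is a superset of the input's, so all originally
    connected path cells stay connected.  A flipped cell with no path
    neighbour forms a small unreachable pocket; such pockets are harmless to
    navigation (the agent can never enter them)."""
    if not 0.0 <= f <= 1.0:
        raise ValueError("loop fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    grid = maze.grid.copy()
    interior = np.zeros_like(grid)
    interior[1:-1, 1:-1] = True
    candidates = interior & ~grid
    flips = candidates & (rng.random(grid.shape) < f)
    grid |= flips
    return Maze(grid, maze.start, maze.start_orientation, maze.goal)


def _bfs_distances(maze: Maze, source: tuple[int, int]) -> dict[tuple[int, int], int]:
    dist = {source: 0}
    queue = deque([source])
    while queue:
        x, y = queue.popleft()
        for dx, dy in _DELTAS.values():
            nxt = (x + dx, y + dy)
            if nxt not in dist and maze.is_path(*nxt):
                dist[nxt] = dist[(x, y)] + 1
                queue.append(nxt)
    return dist


def place_start_goal(maze: Maze, seed: int, min_dist: int) -> Maze:
    """Pick distinct start/goal path cells at BFS distance ≥ min_dist.

    The start orientation is drawn uniformly from the directions with a path
    cell directly ahead (uniform over all four if the start is fully
    enclosed).  Raises PlacementError if no placement satisfies min_dist."""
    cells = maze.path_cells()
    if len(cells) < 2:
        raise ValueError("maze needs at least 2 path cells")
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(len(cells)))
    for i in order:
        start = cells[i]
        dist = _bfs_distances(maze, start)
        goals = [c for c, d in dist.items() if d >= max(min_dist, 1)]
        if not goals:
            continue
        goal = goals[int(rng.integers(len(goals)))]
        open_dirs = [
            d for d in DIRECTIONS
            if maze.is_path(start[0] + _DELTAS[d][0], start[1] + _DELTAS[d][1])
        ]
        pool = open_dirs if open_dirs else list(DIRECTIONS)
        orientation = pool[int(rng.integers(len(pool)))]
        return Maze(maze.grid.copy(), start, orientation, goal)
    raise PlacementError(
        f"no start/goal pair at BFS distance >= {min_dist} exists in this maze"
    )


def enumerate_mazes(
    width: int,
    height: int,
    start: tuple[int, int],
    goal: tuple[int, int],
    start_orientation: str,
) -> Iterator[Maze]:
    """All 2^(W*H - 2) grids with start and goal fixed as path and every other
    cell free over {wall, path}.  Includes unreachable-goal grids.  Guarded to
    W*H ≤ 16."""
    if width * height > 16:
        raise ValueError("enumeration guarded to W*H <= 16")
    if start == goal:
        raise ValueError("start and goal must differ")
    free = [
        (x, y)
        for y in range(height)
        for x in range(width)
        if (x, y) not in (start, goal)
    ]
    for bits in itertools.product((False, True), repeat=len(free)):
        grid = np.zeros((height, width), dtype=bool)
        grid[start[1], start[0]] = True
        grid[goal[1], goal[0]] = True
        for (x, y), b in zip(free, bits):
            grid[y, x] = b
        yield Maze(grid, start, start_orientation, goal)


def shortest_path_steps(maze: Maze) -> Optional[int]:
    """BFS distance start→goal (4-connectivity), or None if unreachable."""
    if maze.start is None or maze.goal is None:
        raise ValueError("maze must have start and goal")
    return _bfs_distances(maze, maze.start).get(maze.goal)


def sample_mazes(params: MazeGenParams, M: int, max_retries_per_maze: int = 20) -> MazeSample:
    """Draw M mazes from the distribution: Prim tree, loop injection, then
    seeded start/goal placement (fresh placement per maze).  Mazes whose
    placement fails the distance constraint are redrawn."""
    if M < 1:
        raise ValueError("M must be >= 1")
    rng = np.random.default_rng(params.seed)
    mazes: list[Maze] = []
    while len(mazes) < M:
        for attempt in range(max_retries_per_maze):
            sub = rng.integers(2**31, size=3)
            raw = _prim_grid(params.width, params.height, np.random.default_rng(int(sub[0])))
            loopy = add_loops(raw, params.loop_fraction, int(sub[1]))
            try:
                mazes.append(
                    place_start_goal(loopy, int(sub[2]), params.effective_min_dist)
                )
                break
            except PlacementError:
                continue
        else:
            raise PlacementError(
                "could not place start/goal after repeated redraws; "
                "min_start_goal_distance is likely infeasible for this size"
            )
    return MazeSample(mazes, params)


# --- text format -----------------------------------------------------------
#
# Header: "W H start_x start_y start_dir goal_x goal_y", then H rows of W
# characters each: '#' wall, '.' path; 'S'/'G' echo start/goal (read as path).

def maze_to_text(maze: Maze) -> str:
    if maze.start is None or maze.goal is None or maze.start_orientation is None:
        raise ValueError("text format requires start, orientation, and goal")
    sx, sy = maze.start
    gx, gy = maze.goal
    header = f"{maze.width} {maze.height} {sx} {sy} {maze.start_orientation} {gx} {gy}"
    rows = []
    for y in range(maze.height):
        row = []
        for x in range(maze.width):
            if (x, y) == maze.start:
                row.append("S")
            elif (x, y) == maze.goal:
                row.append("G")
            else:
                row.append("." if maze.grid[y, x] else "#")
        rows.append("".join(row))
    return "\n".join([header] + rows) + "\n"


def maze_from_text(text: str) -> Maze:
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise ValueError("empty maze text")
    parts = lines[0].split()
    if len(parts) != 7:
        raise ValueError("maze header must be 'W H sx sy sdir gx gy'")
    w, h, sx, sy = int(parts[0]), int(parts[1]), int(parts[2]), int(parts[3])
    sdir = parts[4]
    gx, gy = int(parts[5]), int(parts[6])
    if len(lines) != h + 1:
        raise ValueError(f"expected {h} grid rows, found {len(lines) - 1}")
    grid = np.zeros((h, w), dtype=bool)
    for y, ln in enumerate(lines[1:]):
        if len(ln) != w:
            raise ValueError(f"row {y} has length {len(ln)}, expected {w}")
        for x, ch in enumerate(ln):
            if ch in ".SG":
                grid[y, x] = True
            elif ch != "#":
                raise ValueError(f"bad grid character {ch!r}")
    return Maze(grid, (sx, sy), sdir, (gx, gy))
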