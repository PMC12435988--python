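import numpy as np
import pytest

from blockmaze.mazegen import Maze
from blockmaze.pipeline import build_stimulus_set, exp2_default
from blockmaze.programs import wall_follower


def make_corridor(length: int, orientation: str = "E") -> Maze:
    """1×length horizontal corridor, start at the west end, goal at the east
    end; orientation sets which way the agent initially faces."""
    grid = np.ones((1, length), dtype=bool)
    return Maze(grid, start=(0, 0), start_orientation=orientation, goal=(length - 1, 0))


@pytest.fixture
def corridor3() -> Maze:
    return make_corridor(3)


@pytest.fixture
def note6_program():
    return wall_follower()


@pytest.fixture(scope="session")
def exp2_stimuli():
    """The bundled 60-pair stimulus set (built once per session)."""
    return build_stimulus_set(exp2_default())
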