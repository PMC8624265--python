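"""Grid-world path-following task for generating activity traces.

An agent is rewarded for visiting the cells of a predefined path from a
start cell to a goal cell; 45-degree turns along the path are marked by
turn cells carrying left/right turn symbols.  Three task conditions
differ in how symbols encode turn direction: fixed codes ("0" left,
"1" right), two randomly assigned codes per trial (requiring one bit of
associative memory), or four random two-bit codes per trial.

Geometry: the agent occupies one cell and one of eight compass
headings; left/right motor commands rotate the heading by 45 degrees in
place, forward/reverse translate one cell (diagonals included) along or
against the heading.  Motor decoding: 000 = no movement, 100 = left,
010 = right, 110 = forward, XX1 = reverse.  Moves off the grid clamp to
the border and count as off-path steps.

Sensors: S1 = on a path (non-turn) cell, S2 = off path, S3 = on a turn
cell (exactly one of the three is active), followed by the current
cell's turn-symbol code bits (zero off turn cells).

Fitness: one point per distinct non-start path location visited, plus
the remaining steps if the goal is reached before the time-out (path
length + 50 extra steps by default), minus 0.25 per step spent on empty
cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .agent import Agent
from .trace import ActivityTrace

__all__ = [
    "PathWorld",
    "AgentPose",
    "TrialResult",
    "build_world",
    "step",
    "run_trial",
    "evaluate",
    "EXAMPLE_MAPS",
]

# eight compass headings, clockwise from north, as (drow, dcol)
HEADINGS = [(-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1)]

EMPTY, PATH, LEFT, RIGHT, START, GOAL = ".", "#", "L", "R", "S", "G"


@dataclass
class AgentPose:
    row: int
    col: int
    heading: int  # index into HEADINGS


@dataclass
class PathWorld:
    grid: list                 # list of strings, one per row
    path: list                 # ordered path cells (row, col), start first
    n_symbol_bits: int
    symbol_for: dict           # {"L": code, "R": code}
    flipped: bool = False
    start_heading: int = 0

    @property
    def n_rows(self):
        return len(self.grid)

    @property
    def n_cols(self):
        return len(self.grid[0])

    @property
    def start(self):
        return self.path[0]

    @property
    def goal(self):
        return self.path[-1]

    def cell(self, row, col) -> str:
        return self.grid[row][col]

    def n_sensors(self) -> int:
        return 3 + self.n_symbol_bits

    def reassign_symbols(self, rng) -> "PathWorld":
        """Draw a fresh random turn-symbol assignment (A2/A4 conditions)."""
        codes = rng.permutation(1 << self.n_symbol_bits)[:2]
        return PathWorld(self.grid, self.path, self.n_symbol_bits,
                         {LEFT: int(codes[0]), RIGHT: int(codes[1])},
                         self.flipped, self.start_heading)


def _neighbors(cell):
    r, c = cell
    for dr, dc in HEADINGS:
        yield (r + dr, c + dc)


def _trace_path(grid) -> list:
    """Order the path cells by walking from the start to the goal."""
    cells = {}
    for r, row in enumerate(grid):
        for c, ch in enumerate(row):
            if ch in (PATH, LEFT, RIGHT, START, GOAL):
                cells[(r, c)] = ch
    starts = [p for p, ch in cells.items() if ch == START]
    goals = [p for p, ch in cells.items() if ch == GOAL]
    if len(starts) != 1 or len(goals) != 1:
        raise ValueError("map must contain exactly one start and one goal")
    path = [starts[0]]
    seen = {starts[0]}
    while path[-1] != goals[0]:
        nxt = [p for p in _neighbors(path[-1]) if p in cells and p not in seen]
        if len(nxt) != 1:
            raise ValueError(
                "path cells do not form a single connected sequence "
                f"(at {path[-1]}: {len(nxt)} continuations)"
            )
        path.append(nxt[0])
        seen.add(nxt[0])
    if len(seen) != len(cells):
        raise ValueError("disconnected path cells present in map")
    return path


def _flip_map(map_text: str) -> str:
    """Mirror a map left-right, exchanging left and right turn roles."""
    rows = map_text.strip("\n").splitlines()
    swapped = [
        row[::-1].replace(LEFT, "\0").replace(RIGHT, LEFT).replace("\0", RIGHT)
        for row in rows
    ]
    return "\n".join(swapped)


def build_world(map_text: str, n_symbol_bits: int = 1,
                randomize_symbols: bool = False, seed: int = 0,
                flipped: bool = False) -> PathWorld:
    """Parse a text map into a :class:`PathWorld`.

    Without symbol randomization the codes are fixed: 0 for left and 1
    for right.  With it, an injective assignment of codes to the two
    turn directions is drawn uniformly (redrawn per trial by
    :func:`evaluate`).
    """
    if n_symbol_bits not in (1, 2):
        raise ValueError("n_symbol_bits must be 1 or 2")
    if flipped:
        map_text = _flip_map(map_text)
    rows = [r for r in map_text.strip("\n").splitlines()]
    if not rows or len({len(r) for r in rows}) != 1:
        raise ValueError("map rows must be non-empty and equal length")
    path = _trace_path(rows)
    # initial heading: toward the second path cell
    dr = path[1][0] - path[0][0]
    dc = path[1][1] - path[0][1]
    heading = HEADINGS.index((dr, dc))
    if randomize_symbols:
        rng = np.random.default_rng(seed)
        codes = rng.permutation(1 << n_symbol_bits)[:2]
        symbol_for = {LEFT: int(codes[0]), RIGHT: int(codes[1])}
    else:
        symbol_for = {LEFT: 0, RIGHT: 1}
    return PathWorld(rows, path, n_symbol_bits, symbol_for,
                     flipped=flipped, start_heading=heading)


def _sensor_state(world: PathWorld, pose: AgentPose) -> tuple:
    ch = world.cell(pose.row, pose.col)
    on_turn = ch in (LEFT, RIGHT)
    on_path = ch in (PATH, START, GOAL)
    s1 = 1 if on_path else 0
    s2 = 1 if ch == EMPTY else 0
    s3 = 1 if on_turn else 0
    code = world.symbol_for[ch] if on_turn else 0
    code_bits = tuple((code >> i) & 1 for i in range(world.n_symbol_bits))
    return (s1, s2, s3) + code_bits


def step(world: PathWorld, pose: AgentPose, motor_state) -> tuple:
    """Apply one decoded motor command; return (new pose, sensors, clamped).

    ``motor_state`` is the 3-bit motor reading (m1, m2, m3).
    """
    m1, m2, m3 = (int(b) for b in motor_state)
    row, col, heading = pose.row, pose.col, pose.heading
    clamped = False
    if m3 == 1:
        dr, dc = HEADINGS[heading]
        row, col = row - dr, col - dc
    elif (m1, m2) == (1, 0):
        heading = (heading - 1) % 8
    elif (m1, m2) == (0, 1):
        heading = (heading + 1) % 8
    elif (m1, m2) == (1, 1):
        dr, dc = HEADINGS[heading]
        row, col = row + dr, col + dc
    # clamp to the border
    if not (0 <= row < world.n_rows and 0 <= col < world.n_cols):
        clamped = True
        row = min(max(row, 0), world.n_rows - 1)
        col = min(max(col, 0), world.n_cols - 1)
    new_pose = AgentPose(row, col, heading)
    return new_pose, _sensor_state(world, new_pose), clamped


@dataclass
class TrialResult:
    trace: ActivityTrace
    fitness: float
    visited: int
    completed: bool
    steps: int
    off_path_steps: int = 0
    timeout: int = 0

    def __post_init__(self):
        if self.completed and self.steps > self.timeout:
            raise ValueError("completed trial exceeded its time-out")


def run_trial(agent: Agent, world: PathWorld, initial_state=None,
              timeout_extra: int = 50) -> TrialResult:
    """Run one trial of a deterministic agent in a world.

    The trace records the full system state (sensors as read at each
    step, hidden and motor states as produced by the update) for every
    time step until the goal is reached or the time-out (path length
    plus ``timeout_extra`` steps) expires.
    """
    if world.n_sensors() != agent.n_sensors:
        raise ValueError(
            f"world encodes {world.n_sensors()} sensors, agent has {agent.n_sensors}"
        )
    if not agent.is_deterministic():
        raise ValueError("run_trial requires a deterministic agent")
    k = agent.n_hidden + agent.n_motors
    om = (np.zeros(k, dtype=np.uint8) if initial_state is None
          else np.asarray(initial_state, dtype=np.uint8))
    pose = AgentPose(*world.start, world.start_heading)
    sensors = _sensor_state(world, pose)
    # non-start path locations still to be visited
    to_visit = set(world.path[1:])
    visited = 0
    off_path = 0
    timeout = len(world.path) + timeout_extra
    cols = list(agent.non_sensor_idx)
    weights = 1 << np.arange(agent.n_units)
    records = []
    completed = False
    steps = 0
    for _ in range(timeout):
        full = np.concatenate([np.array(sensors, dtype=np.uint8), om])
        records.append(full)
        idx = int(full @ weights)
        om = (agent.tpm[idx, cols] > 0.5).astype(np.uint8)
        motor_state = om[agent.n_hidden:]
        pose, sensors, clamped = step(world, pose, motor_state)
        steps += 1
        cell = (pose.row, pose.col)
        if cell in to_visit:
            to_visit.discard(cell)
            visited += 1
        if clamped or world.cell(*cell) == EMPTY:
            off_path += 1
        if cell == world.goal:
            completed = True
            break
    fitness = visited - 0.25 * off_path
    if completed:
        fitness += timeout - steps
    trace = ActivityTrace([np.array(records)], labels=list(agent.labels))
    return TrialResult(trace, fitness, visited, completed, steps,
                       off_path_steps=off_path, timeout=timeout)


def evaluate(agent: Agent, worlds, n_repeats: int = 1, seed: int = 0,
             randomize_symbols: bool = False, timeout_extra: int = 50) -> tuple:
    """Evaluate an agent across worlds; return
    (mean fitness, completion fraction, pooled trace).

    With ``randomize_symbols`` the turn-symbol assignment is redrawn
    uniformly for every trial.  The pooled trace preserves trial
    boundaries.
    """
    if not worlds:
        raise ValueError("need at least one world")
    rng = np.random.default_rng(seed)
    fitnesses, completions, trials = [], [], []
    for _ in range(n_repeats):
        for world in worlds:
            w = world.reassign_symbols(rng) if randomize_symbols else world
            result = run_trial(agent, w, timeout_extra=timeout_extra)
            fitnesses.append(result.fitness)
            completions.append(result.completed)
            trials.extend(result.trace.trials)
    pooled = ActivityTrace(trials, labels=list(agent.labels))
    return float(np.mean(fitnesses)), float(np.mean(completions)), pooled


# Four bundled example maps (plus flipped variants via build_world(flipped=True)).
# Paths run start -> goal with 45-degree turns at L/R cells.
EXAMPLE_MAPS = {
    "straight": "S#########G\n",
    "corner": (
        "S###R..\n"
        ".....#.\n"
        "......R\n"
        "......#\n"
        "......G\n"
    ),
    "zigzag": (
        "S##R........\n"
        "....L##R....\n"
        "........L##G\n"
    ),
    "uphill": (
        "........\n"
        "....R##G\n"
        "S##L....\n"
    ),
}
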