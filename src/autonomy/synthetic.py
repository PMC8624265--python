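"""Synthetic agent generators and trace-generating drive protocols.

These generators provide the fixture automata that every measure in the
package can be exercised on: a purely reactive (sensor-driven) agent, a
one-bit associative-memory "latch" agent, closed permutation systems,
and seeded random agents of several archetypes.  The reactive and latch
agents emulate the two poles of the associative-memory contrast in the
path-following task: a reactive controller whose motors are a fixed
function of the current sensor reading, and a controller that must
store the per-trial turn-symbol association in a hidden unit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .agent import Agent, validate_agent
from .trace import ActivityTrace

__all__ = [
    "AgentSpec",
    "build_agent_from_gates",
    "make_reactive_agent",
    "make_latch_agent",
    "make_permutation_system",
    "make_random_agent",
    "latch_drive",
    "random_drive",
]

ARCHETYPES = (
    "reactive",
    "latch",
    "feedforward-chain",
    "recurrent-pair",
    "permutation-closed",
    "random",
)


@dataclass(frozen=True)
class AgentSpec:
    """Recipe for a generated agent: archetype, sizes and seed."""

    archetype: str
    n_sensors: int = 4
    n_hidden: int = 2
    n_motors: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.archetype not in ARCHETYPES:
            raise ValueError(f"unknown archetype {self.archetype!r}")
        if self.n_sensors + self.n_hidden + self.n_motors > 12:
            raise ValueError("agents larger than 12 units are not supported")


def build_agent_from_gates(n_sensors: int, n_hidden: int, n_motors: int, gates: dict) -> Agent:
    """Assemble an agent from per-unit deterministic gates.

    ``gates`` maps each non-sensor unit index to ``(inputs, table)``
    where ``inputs`` is a tuple of source unit indices and ``table`` a
    truth table of length ``2**len(inputs)`` indexed little-endian by
    the input states (first listed input is the least-significant bit).
    Unlisted units are constant 0.
    """
    n = n_sensors + n_hidden + n_motors
    tpm = np.zeros((1 << n, n))
    cm = np.zeros((n, n), dtype=int)
    states = np.arange(1 << n)
    for unit, (inputs, table) in gates.items():
        if unit < n_sensors:
            raise ValueError("sensor units cannot have gates")
        table = np.asarray(table, dtype=float)
        if table.shape != (1 << len(inputs),):
            raise ValueError(f"truth table size mismatch for unit {unit}")
        idx = np.zeros(1 << n, dtype=int)
        for k, j in enumerate(inputs):
            idx |= ((states >> j) & 1) << k
        tpm[:, unit] = table[idx]
        for j in inputs:
            cm[j, unit] = 1
    agent = Agent(n_sensors, n_hidden, n_motors, tpm, cm)
    assert not validate_agent(agent)
    return agent


def make_reactive_agent(n_sensors: int = 4, n_motors: int = 3) -> Agent:
    """Purely reactive agent: each motor copies one sensor, no hidden units.

    Motors at t+1 are a deterministic function of the current sensors
    alone, so the sensor-conditioned autonomy of this agent is zero by
    construction and its connectivity graph has no cycles.
    """
    if n_sensors < 1:
        raise ValueError("need at least one sensor")
    gates = {}
    for j in range(n_motors):
        src = j % n_sensors
        gates[n_sensors + j] = ((src,), np.array([0.0, 1.0]))
    return build_agent_from_gates(n_sensors, 0, n_motors, gates)


def make_latch_agent() -> Agent:
    """One-bit associative-memory agent (4 sensors, 1 hidden, 3 motors).

    Sensor layout follows the path-following encoding: S1 = on-path,
    S2 = off-path, S3 = on-turn/cue, S4 = turn-symbol bit.  The hidden
    unit latches the symbol bit whenever the cue sensor S3 is active and
    otherwise holds its state through a self-loop:

        h' = S4 if S3 else h

    Motors: M1 (left) and M2 (right) fire together as "forward" on path
    cells, and on turn cells pick a direction by comparing the current
    symbol against the stored association (S4 XOR h).  M3 is unused.
    """
    S1, S2, S3, S4, H, M1, M2, M3 = range(8)

    # h' = S4 if S3 else h; inputs (S3, S4, h) little-endian
    latch_table = np.zeros(8)
    for s3 in (0, 1):
        for s4 in (0, 1):
            for h in (0, 1):
                latch_table[s3 + (s4 << 1) + (h << 2)] = s4 if s3 else h

    # M1' = S1 or (S3 and not(S4 xor h)); inputs (S1, S3, S4, h)
    m1_table = np.zeros(16)
    m2_table = np.zeros(16)
    for s1 in (0, 1):
        for s3 in (0, 1):
            for s4 in (0, 1):
                for h in (0, 1):
                    i = s1 + (s3 << 1) + (s4 << 2) + (h << 3)
                    turn_right = s4 ^ h
                    m1_table[i] = 1.0 if (s1 or (s3 and not turn_right)) else 0.0
                    m2_table[i] = 1.0 if (s1 or (s3 and turn_right)) else 0.0

    gates = {
        H: ((S3, S4, H), latch_table),
        M1: ((S1, S3, S4, H), m1_table),
        M2: ((S1, S3, S4, H), m2_table),
    }
    return build_agent_from_gates(4, 1, 3, gates)


def _dependency_cm(tpm: np.ndarray) -> np.ndarray:
    """Minimal connectivity matrix: cm[j, i] = 1 iff column i depends on j."""
    n = tpm.shape[1]
    cm = np.zeros((n, n), dtype=int)
    rows = np.arange(tpm.shape[0])
    for j in range(n):
        low = rows[(rows >> j) & 1 == 0]
        high = low | (1 << j)
        cm[j] = np.any(tpm[low] != tpm[high], axis=0).astype(int)
    return cm


def make_permutation_system(n_units: int, seed: int = 0, permutation=None) -> Agent:
    """Closed deterministic system whose global map permutes the state space.

    With no sensors or motors, every unit is hidden.  Permutation maps
    are the maximally self-determining deterministic systems: their
    effective information equals ``n_units`` bits.  Pass an explicit
    ``permutation`` (e.g. the identity) to fix the map; otherwise it is
    drawn uniformly from S(2**n) with the given seed.
    """
    if not 1 <= n_units <= 8:
        raise ValueError("permutation systems support 1..8 units")
    size = 1 << n_units
    if permutation is None:
        permutation = np.random.default_rng(seed).permutation(size)
    permutation = np.asarray(permutation, dtype=int)
    if sorted(permutation.tolist()) != list(range(size)):
        raise ValueError("not a permutation of the state space")
    tpm = ((permutation[:, None] >> np.arange(n_units)) & 1).astype(float)
    cm = _dependency_cm(tpm)
    return Agent(0, n_units, 0, tpm, cm)


def _random_table(rng, k: int) -> np.ndarray:
    return rng.integers(0, 2, 1 << k).astype(float)


def make_random_agent(spec: AgentSpec) -> Agent:
    """Seeded random deterministic agent of the requested archetype.

    Gate truth tables are sampled uniformly over each unit's declared
    inputs; identical specs produce byte-identical agents.
    """
    rng = np.random.default_rng(spec.seed)
    ns, nh, nm = spec.n_sensors, spec.n_hidden, spec.n_motors

    if spec.archetype == "reactive":
        return make_reactive_agent(ns, nm)
    if spec.archetype == "latch":
        return make_latch_agent()
    if spec.archetype == "permutation-closed":
        return make_permutation_system(max(nh, 1), spec.seed)

    hidden = list(range(ns, ns + nh))
    motors = list(range(ns + nh, ns + nh + nm))
    gates = {}

    if spec.archetype == "feedforward-chain":
        if nh < 1:
            raise ValueError("feedforward-chain needs hidden units")
        # sensors -> first hidden -> ... -> last hidden -> motors; no cycles
        first = hidden[0]
        ins = tuple(range(ns)) or (0,)
        gates[first] = (ins, _random_table(rng, len(ins)))
        for prev, unit in zip(hidden, hidden[1:]):
            gates[unit] = ((prev,), np.array([1.0, 0.0]))  # NOT gate keeps dependence
        for m in motors:
            gates[m] = ((hidden[-1],), _random_table(rng, 1))
        return build_agent_from_gates(ns, nh, nm, gates)

    if spec.archetype == "recurrent-pair":
        if nh < 2:
            raise ValueError("recurrent-pair needs at least two hidden units")
        h1, h2 = hidden[0], hidden[1]
        in1 = tuple(range(min(ns, 2))) + (h2,)
        in2 = (h1,) if ns == 0 else (0, h1)
        gates[h1] = (in1, _random_table(rng, len(in1)))
        gates[h2] = (in2, _random_table(rng, len(in2)))
        for h in hidden[2:]:
            gates[h] = ((h1, h), _random_table(rng, 2))
        for m in motors:
            gates[m] = ((h1, h2), _random_table(rng, 2))
        return build_agent_from_gates(ns, nh, nm, gates)

    if spec.archetype == "random":
        pool = list(range(ns)) + hidden  # admissible sources: sensors and hidden
        for unit in hidden + motors:
            k = int(rng.integers(1, min(4, len(pool)) + 1))
            ins = tuple(sorted(rng.choice(pool, size=k, replace=False).tolist()))
            gates[unit] = (ins, _random_table(rng, k))
        return build_agent_from_gates(ns, nh, nm, gates)

    raise ValueError(f"unhandled archetype {spec.archetype!r}")


def make_na_solver_agent() -> Agent:
    """Deterministic solver for the fixed-symbol path-following condition.

    Sensors (S1 on-path, S2 off-path, S3 on-turn, S4 symbol bit), one
    hidden unit marking "just turned", three motors.  On a turn cell it
    turns once in the direction given by the fixed code (0 = left,
    1 = right), then steps forward; on path cells it steps forward.
    Completes every bundled map and its flipped version.
    """
    S1, S2, S3, S4, H, M1, M2, M3 = range(8)

    h_table = np.zeros(4)       # h' = S3 and not h; inputs (S3, h)
    for s3 in (0, 1):
        for h in (0, 1):
            h_table[s3 + (h << 1)] = 1.0 if (s3 and not h) else 0.0

    m1_table = np.zeros(16)     # inputs (S1, S3, S4, h)
    m2_table = np.zeros(16)
    for s1 in (0, 1):
        for s3 in (0, 1):
            for s4 in (0, 1):
                for h in (0, 1):
                    i = s1 + (s3 << 1) + (s4 << 2) + (h << 3)
                    turning = s3 and not h
                    forward = s1 or (s3 and h)
                    m1_table[i] = 1.0 if (turning and not s4) or forward else 0.0
                    m2_table[i] = 1.0 if (turning and s4) or forward else 0.0

    gates = {
        H: ((S3, H), h_table),
        M1: ((S1, S3, S4, H), m1_table),
        M2: ((S1, S3, S4, H), m2_table),
    }
    return build_agent_from_gates(4, 1, 3, gates)


# -- drive protocols -------------------------------------------------------

def _simulate(agent: Agent, sensor_seq: np.ndarray, init_om: np.ndarray) -> np.ndarray:
    """Run a deterministic agent against a fixed sensor sequence.

    ``sensor_seq`` has shape (T, n_sensors); the returned array has shape
    (T, n_units) where row t holds the sensor state at t and the hidden
    and motor states that resulted from the step t-1 -> t (row 0 holds
    ``init_om``).
    """
    if not agent.is_deterministic():
        raise ValueError("drive protocols require a deterministic agent")
    ns = agent.n_sensors
    T = sensor_seq.shape[0]
    out = np.zeros((T, agent.n_units), dtype=np.uint8)
    out[:, :ns] = sensor_seq
    om = np.array(init_om, dtype=np.uint8)
    cols = list(agent.non_sensor_idx)
    for t in range(T):
        out[t, ns:] = om
        if t + 1 < T:
            full_idx = int(np.dot(out[t], 1 << np.arange(agent.n_units)))
            om = (agent.tpm[full_idx, cols] > 0.5).astype(np.uint8)
    return out


def latch_drive(agent: Agent, n_trials: int = 200, n_steps: int = 20,
                seed: int = 0, balanced: bool = False) -> ActivityTrace:
    """Associative-memory drive protocol for latch-style agents.

    Each trial draws an association bit, presents it once through the
    cue sensors (S3 = 1, S4 = bit) in a warm-up step that precedes the
    recorded activity, then feeds ``n_steps`` of neutral on-path input
    (S1 = 1).  The recorded hidden state therefore carries exactly the
    stored association, and no recorded sensor window reveals it.

    With ``balanced=True`` the two associations alternate so that they
    are exactly equally frequent; otherwise bits are drawn uniformly.
    """
    rng = np.random.default_rng(seed)
    trials = []
    for trial in range(n_trials):
        bit = (trial % 2) if balanced else int(rng.integers(0, 2))
        seq = np.zeros((n_steps + 1, agent.n_sensors), dtype=np.uint8)
        seq[0] = 0
        seq[0, 2] = 1          # cue
        seq[0, 3] = bit        # symbol bit
        seq[1:, 0] = 1         # neutral on-path input afterwards
        full = _simulate(agent, seq, init_om=np.zeros(agent.n_hidden + agent.n_motors))
        trials.append(full[1:])  # recording starts after the cue step
    return ActivityTrace(trials, labels=list(agent.labels))


def random_drive(agent: Agent, n_trials: int = 20, n_steps: int = 100,
                 seed: int = 0) -> ActivityTrace:
    """Drive an agent with i.i.d. uniform random sensor input."""
    rng = np.random.default_rng(seed)
    trials = []
    for _ in range(n_trials):
        seq = rng.integers(0, 2, (n_steps, agent.n_sensors)).astype(np.uint8)
        init = rng.integers(0, 2, agent.n_hidden + agent.n_motors).astype(np.uint8)
        trials.append(_simulate(agent, seq, init))
    return ActivityTrace(trials, labels=list(agent.labels))
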