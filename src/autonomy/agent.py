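"""Data model for TPM-defined sensor/hidden/motor automata.

An agent is a discrete-time, discrete-state network of binary units
partitioned into sensors S, hidden units O and motors M (in that fixed
order).  Its dynamics are fully described by a state-by-node transition
probability matrix: row ``v`` (little-endian state index, unit 0 is the
least-significant bit) and column ``i`` give ``P(unit i = 1 at t+1 | full
state v at t)``.  Sensors are written by the environment, never by the
network, so their TPM columns are stored as all-zero placeholders and
carry no dynamical meaning.  Motors act on the environment but do not
feed back into the network: toggling a motor bit in the current state
never changes any hidden or motor column.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "Agent",
    "Violation",
    "load_agent",
    "save_agent",
    "validate_agent",
    "classify_functional_nodes",
    "condition_on_sensors",
    "sensor_conditioned_map",
    "state_to_index",
    "index_to_state",
    "to_state_by_state",
]


def state_to_index(bits) -> int:
    """Little-endian integer index of a tuple of binary values."""
    idx = 0
    for i, b in enumerate(bits):
        idx += int(b) << i
    return idx


def index_to_state(index: int, n: int) -> tuple:
    """Inverse of :func:`state_to_index` for an ``n``-unit subset."""
    if not 0 <= index < (1 << n):
        raise ValueError(f"index {index} out of range for {n} units")
    return tuple((index >> i) & 1 for i in range(n))


@dataclass
class Agent:
    """A TPM-defined automaton with a sensor/hidden/motor unit partition.

    Attributes
    ----------
    n_sensors, n_hidden, n_motors
        Sizes of the three unit classes.  Units are ordered sensors
        first, then hidden, then motors.
    tpm
        ``(2**n, n)`` float array of per-unit activation probabilities,
        state-by-node form, little-endian row indexing.
    cm
        ``(n, n)`` binary connectivity matrix; ``cm[i, j] == 1`` iff unit
        ``i`` inputs to unit ``j``.
    labels
        Unit names, sensors first.
    """

    n_sensors: int
    n_hidden: int
    n_motors: int
    tpm: np.ndarray
    cm: np.ndarray
    labels: list = field(default_factory=list)

    def __post_init__(self):
        self.tpm = np.asarray(self.tpm, dtype=float)
        self.cm = np.asarray(self.cm, dtype=int)
        n = self.n_units
        if self.tpm.shape != (1 << n, n):
            raise ValueError(
                f"TPM row count mismatch: expected {(1 << n, n)}, got {self.tpm.shape}"
            )
        if self.cm.shape != (n, n):
            raise ValueError(f"cm shape mismatch: expected {(n, n)}, got {self.cm.shape}")
        if np.any(self.tpm < 0) or np.any(self.tpm > 1):
            raise ValueError("TPM entries must lie in [0, 1]")
        if not self.labels:
            self.labels = (
                [f"S{i + 1}" for i in range(self.n_sensors)]
                + [f"O{i + 1}" for i in range(self.n_hidden)]
                + [f"M{i + 1}" for i in range(self.n_motors)]
            )
        if len(self.labels) != n:
            raise ValueError("label count inconsistent with unit count")

    # -- index bookkeeping -------------------------------------------------
    @property
    def n_units(self) -> int:
        return self.n_sensors + self.n_hidden + self.n_motors

    @property
    def sensor_idx(self) -> tuple:
        return tuple(range(self.n_sensors))

    @property
    def hidden_idx(self) -> tuple:
        return tuple(range(self.n_sensors, self.n_sensors + self.n_hidden))

    @property
    def motor_idx(self) -> tuple:
        return tuple(range(self.n_sensors + self.n_hidden, self.n_units))

    @property
    def non_sensor_idx(self) -> tuple:
        return self.hidden_idx + self.motor_idx

    def is_deterministic(self) -> bool:
        cols = self.tpm[:, list(self.non_sensor_idx)]
        return bool(np.all((cols == 0) | (cols == 1)))


class Violation(dict):
    """A named invariant violation with offending units/rows."""

    def __init__(self, invariant: str, detail: str, **info):
        super().__init__(invariant=invariant, detail=detail, **info)

    @property
    def invariant(self) -> str:
        return self["invariant"]


def _toggle_pairs(n: int, j: int):
    """Row indices with bit j clear, and the same rows with bit j set."""
    rows = np.arange(1 << n)
    low = rows[(rows >> j) & 1 == 0]
    return low, low | (1 << j)


def validate_agent(agent: Agent) -> list:
    """Check every structural invariant; return a list of violations.

    An empty list means the agent is well formed.  Violations are
    returned rather than raised so that callers can report all problems
    at once.
    """
    out = []
    n = agent.n_units

    for j in agent.sensor_idx:
        if np.any(agent.tpm[:, j] != 0):
            out.append(
                Violation(
                    "sensor-column-zero",
                    f"sensor unit {j} has a non-zero TPM column; sensor columns are placeholders",
                    unit=j,
                )
            )
        if np.any(agent.cm[:, j] != 0):
            srcs = np.nonzero(agent.cm[:, j])[0].tolist()
            out.append(
                Violation(
                    "sensor-input",
                    f"units {srcs} write to sensor unit {j}",
                    unit=j,
                    sources=srcs,
                )
            )

    ns_cols = list(agent.non_sensor_idx)
    for j in agent.motor_idx:
        if np.any(agent.cm[j, :] != 0):
            dsts = np.nonzero(agent.cm[j, :])[0].tolist()
            out.append(
                Violation(
                    "motor-feedback",
                    f"motor unit {j} has outgoing cm edges to {dsts}",
                    unit=j,
                    targets=dsts,
                )
            )
        low, high = _toggle_pairs(n, j)
        if not np.array_equal(agent.tpm[np.ix_(low, ns_cols)], agent.tpm[np.ix_(high, ns_cols)]):
            bad = low[
                np.any(agent.tpm[np.ix_(low, ns_cols)] != agent.tpm[np.ix_(high, ns_cols)], axis=1)
            ]
            out.append(
                Violation(
                    "motor-feedback",
                    f"hidden/motor columns change when motor bit {j} toggles",
                    unit=j,
                    rows=bad[:8].tolist(),
                )
            )

    # tpm must respect cm: column i invariant to toggling any non-input j
    for i in agent.non_sensor_idx:
        non_inputs = [j for j in range(n) if agent.cm[j, i] == 0]
        for j in non_inputs:
            low, high = _toggle_pairs(n, j)
            if not np.array_equal(agent.tpm[low, i], agent.tpm[high, i]):
                out.append(
                    Violation(
                        "tpm-respects-cm",
                        f"column of unit {i} depends on unit {j}, but cm[{j},{i}] = 0",
                        unit=i,
                        depends_on=j,
                    )
                )
    return out


def classify_functional_nodes(agent: Agent) -> dict:
    """Partition units into functional and non-functional classes.

    Functional sensors output to another unit; functional motors receive
    input; functional hidden units receive input (a self-loop counts)
    and output to *another* unit.  The count of functional units of all
    classes is reported as ``cN``.
    """
    cm = agent.cm
    off_diag_out = cm.copy()
    np.fill_diagonal(off_diag_out, 0)

    sensors = [i for i in agent.sensor_idx if off_diag_out[i, :].any()]
    motors = [i for i in agent.motor_idx if cm[:, i].any()]
    hidden = [
        i
        for i in agent.hidden_idx
        if cm[:, i].any() and off_diag_out[i, :].any()
    ]
    return {
        "sensors": tuple(sensors),
        "hidden": tuple(hidden),
        "motors": tuple(motors),
        "cN": len(sensors) + len(hidden) + len(motors),
    }


def condition_on_sensors(agent: Agent, sensor_state) -> np.ndarray:
    """State-by-state transition table over (hidden, motor) states.

    Returns a ``(2**k, 2**k)`` matrix (``k = n_hidden + n_motors``) whose
    entry ``[om, om']`` is ``p(o', m' | s = sensor_state, o, m)``.  Units
    are conditionally independent given the full current state, so the
    joint row is the product of the per-unit activation probabilities.
    """
    sensor_state = tuple(int(b) for b in sensor_state)
    if len(sensor_state) != agent.n_sensors:
        raise ValueError(
            f"sensor_state has {len(sensor_state)} bits, agent has {agent.n_sensors} sensors"
        )
    k = agent.n_hidden + agent.n_motors
    s_index = state_to_index(sensor_state)
    # rows of the full TPM with sensors fixed: full index = s + om << n_sensors
    rows = s_index + (np.arange(1 << k) << agent.n_sensors)
    p1 = agent.tpm[np.ix_(rows, list(agent.non_sensor_idx))]  # (2^k, k)
    next_states = np.arange(1 << k)
    bits = (next_states[None, :] >> np.arange(k)[:, None]) & 1  # (k, 2^k)
    table = np.ones((1 << k, 1 << k))
    for u in range(k):
        pu = p1[:, u][:, None]
        table *= np.where(bits[u][None, :] == 1, pu, 1.0 - pu)
    return table


def sensor_conditioned_map(agent: Agent, sensor_state) -> np.ndarray:
    """Deterministic (hidden, motor) successor map under a fixed sensor state.

    Only defined for deterministic agents; returns an int array of length
    ``2**(n_hidden + n_motors)``.
    """
    if not agent.is_deterministic():
        raise ValueError("agent has stochastic units; no deterministic map exists")
    sensor_state = tuple(int(b) for b in sensor_state)
    if len(sensor_state) != agent.n_sensors:
        raise ValueError("sensor_state length mismatch")
    k = agent.n_hidden + agent.n_motors
    s_index = state_to_index(sensor_state)
    rows = s_index + (np.arange(1 << k) << agent.n_sensors)
    p1 = agent.tpm[np.ix_(rows, list(agent.non_sensor_idx))].astype(int)
    return (p1 << np.arange(k)).sum(axis=1)


def to_state_by_state(tpm: np.ndarray) -> np.ndarray:
    """Convert a state-by-node TPM to its ``(2**n, 2**n)`` state-by-state form.

    Valid because units are conditionally independent given the previous
    state.  Sensor columns (all zero) map sensors deterministically to 0.
    """
    tpm = np.asarray(tpm, dtype=float)
    n = tpm.shape[1]
    if tpm.shape[0] != 1 << n:
        raise ValueError("TPM row count is not 2**n")
    states = np.arange(1 << n)
    bits = (states[None, :] >> np.arange(n)[:, None]) & 1
    out = np.ones((1 << n, 1 << n))
    for u in range(n):
        pu = tpm[:, u][:, None]
        out *= np.where(bits[u][None, :] == 1, pu, 1.0 - pu)
    return out


# -- serialization ---------------------------------------------------------

def save_agent(agent: Agent, path) -> None:
    """Write an agent as JSON metadata plus TPM/CM CSV files."""
    path = Path(path)
    stem = path.with_suffix("")
    tpm_file = stem.name + "_tpm.csv"
    cm_file = stem.name + "_cm.csv"
    meta = {
        "n_sensors": agent.n_sensors,
        "n_hidden": agent.n_hidden,
        "n_motors": agent.n_motors,
        "labels": list(agent.labels),
        "tpm_file": tpm_file,
        "cm_file": cm_file,
    }
    path.write_text(json.dumps(meta, indent=2) + "\n")
    np.savetxt(path.parent / tpm_file, agent.tpm, delimiter=",", fmt="%.17g")
    np.savetxt(path.parent / cm_file, agent.cm, delimiter=",", fmt="%d")


def load_agent(path) -> Agent:
    """Load an agent from its JSON metadata file.

    The loader enforces the canonical unit ordering (sensors, hidden,
    motors) and all structural invariants; malformed files raise
    ``ValueError`` rather than producing a silently permuted agent.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    meta = json.loads(path.read_text())
    for key in ("n_sensors", "n_hidden", "n_motors", "tpm_file", "cm_file"):
        if key not in meta:
            raise ValueError(f"agent metadata missing field {key!r}")
    tpm = np.loadtxt(path.parent / meta["tpm_file"], delimiter=",", ndmin=2)
    cm = np.loadtxt(path.parent / meta["cm_file"], delimiter=",", ndmin=2)
    n = meta["n_sensors"] + meta["n_hidden"] + meta["n_motors"]
    if tpm.shape[0] != 1 << n:
        raise ValueError(
            f"row count mismatch: TPM has {tpm.shape[0]} rows, expected {1 << n}"
        )
    if tpm.shape[1] != n:
        raise ValueError("partition sizes inconsistent with TPM width")
    agent = Agent(
        n_sensors=meta["n_sensors"],
        n_hidden=meta["n_hidden"],
        n_motors=meta["n_motors"],
        tpm=tpm,
        cm=cm,
        labels=meta.get("labels", []),
    )
    violations = validate_agent(agent)
    if violations:
        raise ValueError(
            "agent file violates invariants: "
            + "; ".join(v["detail"] for v in violations)
        )
    return agent
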