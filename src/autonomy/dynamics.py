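"""Dynamical complexity measures: unique transitions, Lempel-Ziv, transients.

Two families are covered.  Activity-based measures (unique transitions
and the normalized Lempel-Ziv complexity nLZ) operate on recorded
traces.  Perturbational measures iterate a deterministic agent's
sensor-conditioned map from every possible (hidden, motor) state while
holding the sensors fixed, and quantify the resulting transients: their
lengths and the compressibility of their trajectories (nLZ_tr).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .agent import Agent, sensor_conditioned_map
from .trace import ActivityTrace

try:  # JIT-compiled scan; falls back to pure Python transparently
    from numba import njit as _njit
except ImportError:  # pragma: no cover
    _njit = None

__all__ = [
    "unique_transitions",
    "lz76_complexity",
    "NLZResult",
    "nlz",
    "nlz_trace",
    "Transient",
    "TransientSet",
    "perturbational_transients",
    "transient_lengths",
    "nlz_transients",
]


def unique_transitions(trace: ActivityTrace) -> int:
    """Number of distinct ordered full-state transitions within trials."""
    pairs = set()
    for tr in trace.trials:
        if tr.shape[0] < 2:
            continue
        weights = 1 << np.arange(tr.shape[1])
        codes = tr @ weights
        pairs.update(zip(codes[:-1].tolist(), codes[1:].tolist()))
    if not pairs:
        raise ValueError("no within-trial transitions (trials too short)")
    return len(pairs)


def _lz76_scan(s: np.ndarray) -> int:
    # Kaspar-Schuster exhaustive-history scan
    n = s.shape[0]
    c = 1
    i, k, ell = 0, 1, 1
    k_max = 1
    while True:
        if s[i + k - 1] == s[ell + k - 1]:
            k += 1
            if ell + k > n:
                c += 1
                break
        else:
            if k > k_max:
                k_max = k
            i += 1
            if i == ell:
                c += 1
                ell += k_max
                if ell + 1 > n:
                    break
                i, k, k_max = 0, 1, 1
            else:
                k = 1
    return c


if _njit is not None:
    _lz76_scan = _njit(cache=False)(_lz76_scan)


def lz76_complexity(s) -> int:
    """Lempel-Ziv 1976 complexity: number of words in the exhaustive parsing.

    Accepts a string over {0, 1} or a binary sequence.  Scanning left to
    right, a new word is counted whenever the current phrase is not a
    substring of the previously seen material.
    """
    if isinstance(s, str):
        if set(s) - {"0", "1"}:
            raise ValueError("string must be binary")
        bits = np.frombuffer(s.encode(), dtype=np.uint8) - ord("0")
    else:
        bits = np.asarray(s, dtype=np.uint8).ravel()
        if bits.size and bits.max() > 1:
            raise ValueError("string must be binary")
    if bits.size == 0:
        raise ValueError("empty string")
    if bits.size == 1:
        return 1
    return int(_lz76_scan(bits))


@dataclass
class NLZResult:
    """Normalized LZ complexity with its ingredients and a degeneracy flag."""

    value: float
    lz: int
    baseline: float
    degenerate: bool

    def __float__(self):
        return self.value


def nlz(symbols, n_permutations: int = 100, seed: int = 0) -> NLZResult:
    """LZ76 complexity normalized by shuffled-string baselines.

    The baseline is the mean LZ76 complexity of ``n_permutations``
    uniform random permutations of the symbol positions.  A string whose
    symbols are (close to) constant has an uninformative baseline; the
    result is then flagged ``degenerate`` rather than withheld.
    """
    bits = np.asarray([int(b) for b in symbols] if isinstance(symbols, str)
                      else np.asarray(symbols).ravel(), dtype=np.uint8)
    if bits.size < 2:
        raise ValueError("need at least two symbols")
    raw = lz76_complexity(bits)
    rng = np.random.default_rng(seed)
    baselines = []
    for _ in range(n_permutations):
        baselines.append(lz76_complexity(rng.permutation(bits)))
    baseline = float(np.mean(baselines))
    degenerate = bits.min() == bits.max()
    return NLZResult(raw / baseline, raw, baseline, degenerate)


def _flatten(array2d: np.ndarray, order: str) -> np.ndarray:
    """Flatten a (time, units) activity array to one dimension.

    ``order='space'`` concatenates each time step's unit vector
    (time-major); ``order='time'`` concatenates each unit's full time
    series (unit-major).
    """
    if order == "space":
        return array2d.ravel(order="C")
    if order == "time":
        return array2d.ravel(order="F")
    raise ValueError("order must be 'time' or 'space'")


def nlz_trace(trace: ActivityTrace, order: str = "space", units=None,
              n_permutations: int = 100, seed: int = 0) -> NLZResult:
    """nLZ of recorded activity, reshaped in time or space.

    Trials are concatenated into one long string (trial boundaries are
    immaterial for compression of the pooled activity).
    """
    cols = list(units) if units is not None else list(range(trace.n_units))
    stacked = np.vstack([tr[:, cols] for tr in trace.trials])
    return nlz(_flatten(stacked, order), n_permutations, seed)


@dataclass
class Transient:
    """One perturbational trajectory under a fixed sensor state."""

    sensor_index: int
    start_state: int
    trajectory: list          # (hidden, motor) state indices until first revisit
    transient_length: int     # steps strictly before the attractor is entered
    attractor: tuple          # states on the fixed point / limit cycle


class TransientSet(list):
    """All transients of an agent (every sensor state x every start state)."""

    @property
    def lengths(self) -> np.ndarray:
        return np.array([t.transient_length for t in self])


def perturbational_transients(agent: Agent) -> TransientSet:
    """Iterate the sensor-conditioned map from every (hidden, motor) state.

    For each fixed sensor state the deterministic map over the
    2**(n_hidden + n_motors) internal states is iterated until a state
    repeats; the steps before the first revisited state form the
    transient, the remainder the attractor (fixed point or cycle).
    """
    if not agent.is_deterministic():
        raise ValueError("transients are defined for deterministic agents only")
    k = agent.n_hidden + agent.n_motors
    out = TransientSet()
    for s_index in range(1 << agent.n_sensors):
        sensor_state = tuple((s_index >> i) & 1 for i in range(agent.n_sensors))
        nxt = sensor_conditioned_map(agent, sensor_state)
        for start in range(1 << k):
            traj = [start]
            seen = {start: 0}
            state = start
            while True:
                state = int(nxt[state])
                if state in seen:
                    entry = seen[state]
                    out.append(
                        Transient(
                            sensor_index=s_index,
                            start_state=start,
                            trajectory=traj,
                            transient_length=entry,
                            attractor=tuple(traj[entry:]),
                        )
                    )
                    break
                seen[state] = len(traj)
                traj.append(state)
    return out


def transient_lengths(agent: Agent) -> tuple:
    """(average, maximum) transient length over all perturbations."""
    lengths = perturbational_transients(agent).lengths
    return float(lengths.mean()), int(lengths.max())


def nlz_transients(agent: Agent, order: str = "space",
                   n_permutations: int = 100, seed: int = 0) -> NLZResult:
    """nLZ of the concatenated perturbational transient trajectories.

    Trajectories are concatenated in a fixed order (sensor index
    ascending, then start state ascending), decoded to binary unit
    vectors, reshaped per ``order`` and passed through :func:`nlz`.
    """
    transients = perturbational_transients(agent)
    k = agent.n_hidden + agent.n_motors
    rows = []
    for tr in transients:
        states = np.array(tr.trajectory, dtype=int)
        rows.append(((states[:, None] >> np.arange(k)) & 1).astype(np.uint8))
    stacked = np.vstack(rows)
    return nlz(_flatten(stacked, order), n_permutations, seed)
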