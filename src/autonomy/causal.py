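"""Perturbational (interventional) measures of self-determination.

Unlike the observational measures, these quantities are computed from
the agent's TPM under maximum-entropy interventions, so they reflect
the mechanistic constraints of the substrate rather than the visited
distribution.  Sensors are treated as background drive: they are set to
independent maximum-entropy states and conditioned on, which evaluates
the system's self-determination above the direct influence of its
inputs (for a closed system this reduces to the standard effective
information over the uniform input ensemble).
"""

from __future__ import annotations

import math

import numpy as np

from .agent import Agent, sensor_conditioned_map
from .trace import ActivityTrace, entropy

__all__ = [
    "effective_information",
    "causal_autonomy",
    "state_average",
]


def _conditional_table(agent: Agent, outputs) -> np.ndarray:
    """(2**n, 2**k) table of p(outputs at t+1 | full state at t)."""
    outputs = list(outputs)
    k = len(outputs)
    p1 = agent.tpm[:, outputs]  # (2^n, k)
    out_states = np.arange(1 << k)
    bits = (out_states[None, :] >> np.arange(k)[:, None]) & 1  # (k, 2^k)
    table = np.ones((agent.tpm.shape[0], 1 << k))
    for u in range(k):
        pu = p1[:, u][:, None]
        table *= np.where(bits[u][None, :] == 1, pu, 1.0 - pu)
    return table


def _row_entropies(table: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        logs = np.where(table > 0, np.log2(np.where(table > 0, table, 1.0)), 0.0)
    return -(table * logs).sum(axis=1)


def effective_information(agent: Agent, outputs=None) -> float:
    """Effective information of the system over hidden+motor outputs (bits).

    EI = H(OM_t | S-hat_{t-1}) - H(OM_t | V-hat_{t-1}): the whole
    previous state is perturbed to maximum entropy and the sensor drive
    is conditioned on, so EI measures how much the system's own previous
    internal state constrains its next state.  Equivalently, the
    sensor-state average of |Omega|^-1 sum_v D_KL(p(out|v) || p(out))
    over the sensor-conditioned transition tables; for closed systems
    (no sensors) this is the classic uniform-perturbation EI, which
    reaches ``n`` bits exactly for state-space permutations.
    """
    outputs = list(outputs) if outputs is not None else list(agent.non_sensor_idx)
    table = _conditional_table(agent, outputs)
    row_h = _row_entropies(table)
    ns = agent.n_sensors
    k_rest = agent.n_units - ns
    ei = 0.0
    for s in range(1 << ns):
        rows = s + (np.arange(1 << k_rest) << ns)
        avg = table[rows].mean(axis=0)
        ei += entropy(avg) - row_h[rows].mean()
    return ei / (1 << ns)


def causal_autonomy(agent: Agent, m: int = 4) -> float:
    """Interventional autonomy A-hat_m^S (bits).

    The internal state at t-m and the sensor states at every step
    t-m .. t-1 are independently perturbed to maximum entropy and the
    ensemble is propagated through the TPM exactly:

        A-hat_m^S = H(OM_t | S-hat window) - H(OM_t | V-hat_{t-1}).

    For m=1 this equals :func:`effective_information` exactly; for
    deterministic agents the second term is zero.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    if not agent.is_deterministic():
        raise NotImplementedError("causal autonomy is implemented for deterministic agents")
    ns = agent.n_sensors
    k = agent.n_hidden + agent.n_motors
    size = 1 << k
    maps = [sensor_conditioned_map(agent, tuple((s >> i) & 1 for i in range(ns)))
            for s in range(1 << ns)]
    # propagate the uniform internal ensemble under every sensor sequence,
    # merging sequences that have become indistinguishable
    start = np.ones(size)  # counts over internal states
    pool = {start.tobytes(): (start, 1.0)}
    for _ in range(m):
        nxt: dict = {}
        for counts, weight in pool.values():
            for s_map in maps:
                new = np.bincount(s_map, weights=counts, minlength=size)
                key = new.tobytes()
                if key in nxt:
                    nxt[key] = (nxt[key][0], nxt[key][1] + weight)
                else:
                    nxt[key] = (new, weight)
        pool = nxt
    total_weight = sum(w for _, w in pool.values())
    first_term = sum(
        w * entropy(counts / counts.sum()) for counts, w in pool.values()
    ) / total_weight
    return first_term  # deterministic: H(OM_t | V-hat_{t-1}) = 0


def state_average(measure, agent: Agent, trace: ActivityTrace, on: str = "states"):
    """Occurrence-weighted average of a state- or transition-level measure.

    ``measure(agent, state)`` (``on='states'``) or
    ``measure(agent, (state_prev, state_next))`` (``on='transitions'``)
    is evaluated once per distinct observed state/within-trial
    transition and averaged with the observed visit frequencies as
    weights.  NaN values (measure undefined in a state) are excluded
    with renormalized weights; the result is NaN if no state yields a
    value.
    """
    counts: dict = {}
    if on == "states":
        for tr in trace.trials:
            for row in tr:
                key = tuple(int(b) for b in row)
                counts[key] = counts.get(key, 0) + 1
    elif on == "transitions":
        for tr in trace.trials:
            for a, b in zip(tr[:-1], tr[1:]):
                key = (tuple(int(x) for x in a), tuple(int(x) for x in b))
                counts[key] = counts.get(key, 0) + 1
        if not counts:
            raise ValueError("no within-trial transitions in trace")
    else:
        raise ValueError("on must be 'states' or 'transitions'")

    total, acc = 0.0, 0.0
    for key, weight in counts.items():
        value = measure(agent, key)
        if value is None or (isinstance(value, float) and math.isnan(value)):
            continue
        acc += weight * value
        total += weight
    return acc / total if total > 0 else math.nan
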