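"""Observational information measures on recorded agent activity.

All quantities are plug-in estimates (base-2, no bias correction) over
an :class:`~autonomy.trace.ActivityTrace`, with the agent's sensors
standing in for the environment: the "system" is the set of hidden and
motor units (O, M) unless stated otherwise.  The panel covers

* sensor-motor mutual information  I(S_t; M_{t+d})
* predictive information (TDMI)    I(V_{t-1}; V_t)
* sensor-conditioned autonomy      A_m^S = H(OM_t | S-window)
                                         - H(OM_t | OM_{t-1}, S-window)
* information flow / closure       J = I(OM_{t+1}; S_t | OM_t)
* non-trivial information closure  NTIC_m = I_pred - A_m^S
* multi-information (total correlation) and TSE complexity.

Lag windows never cross trial boundaries; the first m steps of each
trial are dropped from lag-m statistics.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np

from .agent import Agent
from .trace import ActivityTrace, entropy

__all__ = [
    "joint_entropy",
    "conditional_entropy",
    "mutual_information",
    "conditional_mutual_information",
    "sensor_motor_mi",
    "predictive_information",
    "autonomy_A",
    "information_closure_J",
    "ntic",
    "multi_information",
    "tse_complexity",
    "system_entropy",
]


def _H(samples: np.ndarray, cols) -> float:
    """Plug-in joint entropy of selected integer-coded columns."""
    cols = list(cols)
    if not cols:
        return 0.0
    sub = samples[:, cols]
    _, counts = np.unique(sub, axis=0, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def joint_entropy(trace: ActivityTrace, units, lag: int = 0) -> float:
    """H of the joint state of ``units`` (single time slice)."""
    samples = trace.lagged_samples([(units, lag)])
    return _H(samples, [0])


def conditional_entropy(samples: np.ndarray, target, given) -> float:
    return _H(samples, list(target) + list(given)) - _H(samples, given)


def mutual_information(samples: np.ndarray, a, b) -> float:
    return _H(samples, a) + _H(samples, b) - _H(samples, list(a) + list(b))


def conditional_mutual_information(samples: np.ndarray, a, b, given) -> float:
    g = list(given)
    return (
        _H(samples, list(a) + g)
        + _H(samples, list(b) + g)
        - _H(samples, list(a) + list(b) + g)
        - _H(samples, g)
    )


def _system_units(agent: Agent, scope: str):
    if scope == "om":
        return list(agent.non_sensor_idx)
    if scope == "full":
        return list(range(agent.n_units))
    raise ValueError("scope must be 'om' or 'full'")


def sensor_motor_mi(trace: ActivityTrace, agent: Agent, d: int = 1) -> float:
    """I(S_t; M_{t+d}) from pooled within-trial pairs (bits)."""
    if d < 1:
        raise ValueError("d must be >= 1")
    samples = trace.lagged_samples([(agent.motor_idx, 0), (agent.sensor_idx, d)])
    return mutual_information(samples, [1], [0])


def predictive_information(trace: ActivityTrace, agent: Agent, scope: str = "om",
                           burn_in: int = 1) -> float:
    """Time-delayed mutual information I(V_{t-1}; V_t) of the system.

    ``scope='om'`` evaluates the hidden+motor system (the default,
    consistent with the sensors-for-environment substitution);
    ``scope='full'`` includes the sensors.  ``burn_in`` sets how many
    initial steps of each trial are excluded (>= 1; pass m to align the
    sample set with lag-m measures).
    """
    if burn_in < 1:
        raise ValueError("burn_in must be >= 1")
    units = _system_units(agent, scope)
    samples = trace.lagged_samples([(units, 0), (units, 1), (units, burn_in)])
    return mutual_information(samples, [0], [1])


def autonomy_A(trace: ActivityTrace, agent: Agent, m: int = 4) -> float:
    """Sensor-conditioned autonomy A_m^S (bits).

    A_m^S = H(OM_t | S_{t-1..t-m}) - H(OM_t | OM_{t-1}, S_{t-1..t-m});
    the second term vanishes for deterministic agents, where the measure
    reduces to the residual uncertainty of the system state given the
    last m sensor readings.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    om = list(agent.non_sensor_idx)
    slots = [(om, 0), (om, 1)] + [(agent.sensor_idx, lag) for lag in range(1, m + 1)]
    samples = trace.lagged_samples(slots)
    window = list(range(2, 2 + m))
    return conditional_entropy(samples, [0], window) - conditional_entropy(
        samples, [0], [1] + window
    )


def information_closure_J(trace: ActivityTrace, agent: Agent) -> float:
    """Information flow from the sensors into the system (bits).

    J = I(OM_{t+1}; S_t | OM_t); zero indicates informational closure.
    """
    om = list(agent.non_sensor_idx)
    samples = trace.lagged_samples([(om, 0), (om, 1), (agent.sensor_idx, 1)])
    return conditional_mutual_information(samples, [0], [2], [1])


def ntic(trace: ActivityTrace, agent: Agent, m: int = 4) -> float:
    """Non-trivial information closure NTIC_m (bits).

    NTIC_m = I(OM_t; S-window) - I(OM_t; S-window | OM_{t-1}), which is
    algebraically identical to I_pred(OM) - A_m^S on the same pooled
    sample set.  Can be negative when sensors and system jointly
    determine the next state.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    om = list(agent.non_sensor_idx)
    slots = [(om, 0), (om, 1)] + [(agent.sensor_idx, lag) for lag in range(1, m + 1)]
    samples = trace.lagged_samples(slots)
    window = list(range(2, 2 + m))
    return mutual_information(samples, [0], window) - conditional_mutual_information(
        samples, [0], window, [1]
    )


def system_entropy(trace: ActivityTrace, agent: Agent, scope: str = "om") -> float:
    """Entropy H of the observed system-state distribution (bits)."""
    return joint_entropy(trace, _system_units(agent, scope))


def multi_information(trace: ActivityTrace, units) -> float:
    """Total correlation MI(V) = sum_i H(V_i) - H(V) over ``units`` (bits)."""
    units = list(units)
    if len(units) < 2:
        raise ValueError("multi-information needs at least two units")
    samples = trace.lagged_samples([([u], 0) for u in units])
    k = len(units)
    return sum(_H(samples, [i]) for i in range(k)) - _H(samples, list(range(k)))


def tse_complexity(trace: ActivityTrace, units) -> float:
    """TSE complexity over ``units`` (bits), by exhaustive subset enumeration.

    C_TSE = sum_{k=1..n} [ <H(subset of size k)> - (k/n) H(V) ]; zero for
    independent units, maximal when small subsets are informative but the
    whole is strongly constrained.
    """
    units = list(units)
    n = len(units)
    if n < 2:
        raise ValueError("TSE needs at least two units")
    if n > 12:
        raise ValueError("exhaustive subset enumeration limited to n <= 12")
    samples = trace.lagged_samples([([u], 0) for u in units])
    h_full = _H(samples, list(range(n)))
    total = 0.0
    for k in range(1, n + 1):
        subset_h = [_H(samples, list(c)) for c in combinations(range(n), k)]
        total += float(np.mean(subset_h)) - (k / n) * h_full
    return total
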