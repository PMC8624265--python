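"""Actual causation: what caused what in one observed transition.

For a transition v_{t-1} -> v_t, the causal strength alpha_c that an
occurrence y_t (a subset of units in their time-t state) specifies
about a candidate cause x_{t-1} is the irreducibility of the link
between them: the log-ratio of the interventional probability of
x_{t-1} given y_t to the same probability under the minimal partition
of the link.  The actual cause x*_{t-1} maximizes alpha_c over
candidate causes.  Shapley values attribute alpha_c fairly across the
units of the actual cause, which yields the relative contribution of
hidden units to the causes of the agent's motor state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from itertools import combinations

import numpy as np

from .agent import Agent, classify_functional_nodes
from .iit import EPSILON, _bipartitions_unordered, _directed_bipartitions

__all__ = [
    "Occurrence",
    "CausalAccount",
    "actual_cause",
    "causal_account",
    "alpha_ratio_hidden",
]


@dataclass
class Occurrence:
    """One occurrence y_t with its actual cause and attribution."""

    units: tuple          # global indices of the occurrence at time t
    state: tuple          # their time-t states
    cause_units: tuple    # actual cause x*_{t-1} (empty if alpha = 0)
    cause_state: tuple
    alpha: float
    shapley: dict         # cause unit -> exact Shapley value of alpha


@dataclass
class CausalAccount:
    """Actual causes of all sub-occurrences of one motor occurrence."""

    before_state: tuple
    after_state: tuple
    occurrences: list

    @property
    def total_alpha(self) -> float:
        return sum(o.alpha for o in self.occurrences)


class _TransitionEngine:
    """Interventional probabilities for one transition context.

    ``cause_scope`` lists the units whose t-1 states are candidate
    causes; units outside it are background conditions frozen at the
    before-state.
    """

    def __init__(self, agent: Agent, before_state, cause_scope):
        self.agent = agent
        self.before = tuple(int(b) for b in before_state)
        self.scope = tuple(sorted(cause_scope))
        n_all = agent.n_units
        scope_set = set(self.scope)
        self._p1 = {}
        for j in agent.non_sensor_idx:
            col = agent.tpm[:, j].reshape((2,) * n_all, order="F")
            for i in range(n_all):
                if i not in scope_set:  # background conditioning, axis kept
                    col = np.take(col, [self.before[i]], axis=i)
            col = np.broadcast_to(col, (2,) * n_all)
            col = col[tuple(0 if i not in scope_set else slice(None)
                            for i in range(n_all))]
            self._p1[j] = np.ascontiguousarray(col)  # axes = scope order

    def likelihood(self, occ_units, occ_state, x_units):
        """pi(y | x) over all states x of ``x_units``: product over occurrence
        units of their activation probability, with non-candidate inputs
        marginalized uniformly."""
        x_units = tuple(sorted(x_units))
        x_pos = [self.scope.index(u) for u in x_units]
        other = tuple(a for a in range(len(self.scope))
                      if a not in x_pos)
        like = np.ones((2,) * len(x_units))
        for u, s in zip(occ_units, occ_state):
            f = self._p1[u] if s else 1.0 - self._p1[u]
            g = f.mean(axis=other) if other else f
            # reorder axes to x_units order (they are scope-ordered already)
            like = like * g
        return like.ravel(order="F")

    def cause_probability(self, occ_units, occ_state, x_units, x_state):
        """pi(x | y): Bayes over the uniform prior on the candidate units."""
        if not x_units:
            return 1.0
        like = self.likelihood(occ_units, occ_state, x_units)
        total = like.sum()
        if total == 0:
            return 0.0
        idx = 0
        for k, s in enumerate(x_state):
            idx |= int(s) << k
        return float(like[idx] / total)

    def alpha(self, occ_units, occ_state, x_units, x_state):
        """Causal strength of the link x_{t-1} -> y_t: minimal-partition
        log-ratio of cause probabilities; 0 if reducible or contrary."""
        occ = tuple(occ_units)
        x_units = tuple(x_units)
        p = self.cause_probability(occ, occ_state, x_units, x_state)
        if p == 0:
            return 0.0
        state_of = dict(zip(x_units, x_state))
        occ_state_of = dict(zip(occ, occ_state))
        alpha_min = math.inf
        for n0, n1 in _bipartitions_unordered(occ):
            for d0, d1 in _directed_bipartitions(x_units):
                if not ((n0 or d0) and (n1 or d1)):
                    continue
                p_part = 1.0
                for nk, dk in ((n0, d0), (n1, d1)):
                    if not dk:
                        continue
                    p_part *= self.cause_probability(
                        nk, tuple(occ_state_of[u] for u in nk),
                        dk, tuple(state_of[u] for u in dk),
                    )
                if p_part == 0:
                    continue  # partition assigns zero probability; infinitely worse
                a = math.log2(p / p_part)
                if abs(a) <= EPSILON or a < 0:
                    return 0.0
                alpha_min = min(alpha_min, a)
        return 0.0 if math.isinf(alpha_min) else alpha_min


def _consistent(agent: Agent, before_state, after_state) -> bool:
    row = 0
    for i, b in enumerate(before_state):
        row |= int(b) << i
    for j in agent.non_sensor_idx:
        p = agent.tpm[row, j]
        if after_state[j] == 1 and p == 0:
            return False
        if after_state[j] == 0 and p == 1:
            return False
    return True


def actual_cause(agent: Agent, transition, occurrence_units, cause_scope=None) -> Occurrence:
    """Actual cause of one occurrence in an observed transition (public form)."""
    occ, _ = _actual_cause(agent, transition, occurrence_units, cause_scope)
    return occ


def _actual_cause(agent: Agent, transition, occurrence_units, cause_scope=None):
    """Actual cause of one occurrence in an observed transition.

    ``transition`` is ``(v_before, v_after)`` (full states);
    ``occurrence_units`` are the global indices whose time-t state forms
    the occurrence y_t.  Candidate causes range over all non-empty
    subsets of ``cause_scope`` (default: functional sensors and hidden
    units) in their time-(t-1) state; candidates containing units
    without a connection to the occurrence are exactly reducible and
    skipped.  Returns an :class:`Occurrence` (without attribution).
    """
    before, after = transition
    if not _consistent(agent, before, after):
        raise ValueError("transition is inconsistent with the agent's TPM")
    if cause_scope is None:
        cls = classify_functional_nodes(agent)
        cause_scope = cls["sensors"] + cls["hidden"]
    occ_units = tuple(sorted(occurrence_units))
    occ_state = tuple(int(after[u]) for u in occ_units)
    engine = _TransitionEngine(agent, before, cause_scope)
    connected = [u for u in engine.scope
                 if any(agent.cm[u, y] for y in occ_units)]
    best_alpha, best_x = 0.0, ()
    for x_units in _all_subsets(connected):
        x_state = tuple(int(before[u]) for u in x_units)
        a = engine.alpha(occ_units, occ_state, x_units, x_state)
        # ties prefer the larger candidate cause, then the first enumerated
        if a > best_alpha + EPSILON or (
            abs(a - best_alpha) <= EPSILON and a > EPSILON
            and len(x_units) > len(best_x)
        ):
            best_alpha, best_x = a, x_units
    return Occurrence(
        units=occ_units,
        state=occ_state,
        cause_units=best_x,
        cause_state=tuple(int(before[u]) for u in best_x),
        alpha=best_alpha,
        shapley={},
    ), engine


def _all_subsets(units):
    units = sorted(units)
    for k in range(1, len(units) + 1):
        yield from combinations(units, k)


def _shapley(engine: _TransitionEngine, occ_units, occ_state, cause_units, before):
    """Exact Shapley attribution of alpha over the units of the actual cause.

    The value function of a coalition T is the causal strength of the
    link from T (in its before-state) to the occurrence; efficiency
    guarantees the values sum to alpha of the full cause.
    """
    players = tuple(cause_units)
    p = len(players)

    @lru_cache(maxsize=None)
    def value(subset: tuple) -> float:
        if not subset:
            return 0.0
        return engine.alpha(
            occ_units, occ_state, subset, tuple(int(before[u]) for u in subset)
        )

    fact = math.factorial
    shap = {u: 0.0 for u in players}
    for u in players:
        rest = tuple(v for v in players if v != u)
        for k in range(len(rest) + 1):
            w = fact(k) * fact(p - k - 1) / fact(p)
            for t in combinations(rest, k):
                shap[u] += w * (
                    value(tuple(sorted(t + (u,)))) - value(tuple(sorted(t)))
                )
    return shap


def causal_account(agent: Agent, transition, cause_scope=None) -> CausalAccount:
    """Actual causes of every sub-occurrence of the motor state.

    The account is compositional: every non-empty subset of the motor
    units (in its time-t state) is treated as an occurrence, its actual
    cause identified, and alpha attributed to the cause's units by exact
    Shapley values.
    """
    before, after = transition
    occurrences = []
    for occ_units in _all_subsets(agent.motor_idx):
        occ, engine = _actual_cause(agent, transition, occ_units, cause_scope)
        if occ.alpha > EPSILON and occ.cause_units:
            occ.shapley = _shapley(engine, occ.units, occ.state,
                                   occ.cause_units, before)
        occurrences.append(occ)
    return CausalAccount(tuple(before), tuple(after), occurrences)


def alpha_ratio_hidden(agent: Agent, transition) -> float:
    """Relative contribution of hidden units to the causes of the motors.

    Ratio of the summed Shapley mass on hidden units to the summed
    causal strength over all motor occurrences of one transition; 1.0
    when motors are caused from within, 0.0 when caused by the sensors
    alone, NaN when no occurrence has a cause.
    """
    account = causal_account(agent, transition)
    hidden = set(agent.hidden_idx)
    total = account.total_alpha
    if total <= 0:
        return math.nan
    hidden_mass = sum(
        v for occ in account.occurrences for u, v in occ.shapley.items()
        if u in hidden
    )
    return hidden_mass / total
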