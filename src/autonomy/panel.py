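"""Measure panel: every autonomy measure for one agent, plus aggregation.

The panel computes the full set of structural, informational, causal
and dynamical measures for an agent and a recorded activity trace,
under one configuration (lags, permutation counts, seeds).  Measures
that are undefined for an agent (for example transient-based measures
of a stochastic agent) are recorded as missing together with the
reason, never silently as zero.  A collection of panels supports a
pairwise-complete Pearson correlation analysis.
"""

from __future__ import annotations

import json
import math
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import causal, dynamics, information, structural
from .actual_causation import alpha_ratio_hidden
from .agent import Agent, classify_functional_nodes
from .iit import major_complex, sum_phi_whole
from .trace import ActivityTrace

__all__ = ["PanelConfig", "MeasurePanel", "compute_panel", "correlation_matrix",
           "MEASURE_NAMES"]

#: Fixed measure vocabulary (panel schema version 1).
MEASURE_NAMES = [
    "cN", "len_LSCC", "len_LWCC", "deg_centrality", "betw_centrality",
    "flow_hierarchy",
    "H", "I_pred", "I_SMMI", "A_4", "NTIC_4", "IC", "MI", "TSE",
    "EI", "A_4c", "sum_phi", "Phi_max", "sum_phi_MC", "alpha_ratio_hidden",
    "uniqueT", "nLZ_space", "nLZ_time", "nLZ_tr_space", "nLZ_tr_time",
    "avTL", "mTL",
]


@dataclass
class PanelConfig:
    """Knobs shared by all panel measures.

    ``m`` is the sensor-history length for A_m / NTIC_m / A-hat_m,
    ``d`` the sensor-motor lag, ``n_permutations`` the shuffle count of
    the nLZ baseline, ``seed`` the seed for those shuffles.
    """

    m: int = 4
    d: int = 1
    n_permutations: int = 100
    seed: int = 0
    measures: list = field(default_factory=lambda: list(MEASURE_NAMES))


@dataclass
class MeasurePanel:
    """Named measure -> value map for one agent."""

    agent_id: str
    values: dict
    missing: dict = field(default_factory=dict)
    config: dict = field(default_factory=dict)
    runtimes: dict = field(default_factory=dict)
    schema_version: int = 1

    def to_json(self, path=None) -> str:
        payload = {
            "agent_id": self.agent_id,
            "schema_version": self.schema_version,
            "values": {k: self.values[k] for k in sorted(self.values)},
            "missing": self.missing,
            "config": self.config,
        }
        text = json.dumps(payload, indent=2, sort_keys=True, allow_nan=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, name=self.agent_id)


def _hidden_state_cache(agent: Agent, fn):
    """Memoize a state measure on the bits that can influence it
    (sensors and hidden units; motors feed nothing back)."""
    cache = {}
    relevant = list(agent.sensor_idx + agent.hidden_idx)

    def wrapped(a, state):
        key = tuple(state[u] for u in relevant)
        if key not in cache:
            cache[key] = fn(a, state)
        return cache[key]

    return wrapped


def compute_panel(agent: Agent, trace: ActivityTrace, config: PanelConfig = None,
                  agent_id: str = "agent") -> MeasurePanel:
    """Compute the full measure panel for one agent and trace."""
    config = config or PanelConfig()
    if trace.n_units != agent.n_units:
        raise ValueError("trace unit count does not match the agent")
    values, missing, runtimes = {}, {}, {}
    functional = classify_functional_nodes(agent)
    func_units = list(functional["sensors"] + functional["hidden"] + functional["motors"])
    deterministic = agent.is_deterministic()

    def record(name, fn):
        if name not in config.measures:
            return
        t0 = time.perf_counter()
        try:
            values[name] = float(fn())
        except Exception as exc:  # undefined for this agent/trace
            missing[name] = str(exc)
        runtimes[name] = time.perf_counter() - t0

    # structural ----------------------------------------------------------
    spanel = structural.structural_panel(agent)
    for name in ("cN", "len_LSCC", "len_LWCC", "deg_centrality",
                 "betw_centrality", "flow_hierarchy"):
        record(name, lambda name=name: spanel[name])

    # informational -------------------------------------------------------
    record("H", lambda: information.system_entropy(trace, agent))
    record("I_pred", lambda: information.predictive_information(trace, agent))
    record("I_SMMI", lambda: information.sensor_motor_mi(trace, agent, d=config.d))
    record("A_4", lambda: information.autonomy_A(trace, agent, m=config.m))
    record("NTIC_4", lambda: information.ntic(trace, agent, m=config.m))
    record("IC", lambda: information.information_closure_J(trace, agent))
    record("MI", lambda: information.multi_information(trace, func_units))
    record("TSE", lambda: information.tse_complexity(trace, func_units))

    # causal --------------------------------------------------------------
    record("EI", lambda: causal.effective_information(agent))
    record("A_4c", lambda: causal.causal_autonomy(agent, m=config.m))

    shared_cache: dict = {}

    def _sum_phi(a, state):
        return sum_phi_whole(a, state, shared_cache=shared_cache)[0]

    record("sum_phi", lambda: causal.state_average(
        _hidden_state_cache(agent, _sum_phi), agent, trace, on="states"))

    mc_cache = _hidden_state_cache(agent, lambda a, s: major_complex(a, s))
    record("Phi_max", lambda: causal.state_average(
        lambda a, s: mc_cache(a, s).phi, agent, trace, on="states"))
    record("sum_phi_MC", lambda: causal.state_average(
        lambda a, s: mc_cache(a, s).sum_phi, agent, trace, on="states"))

    ar_cache = {}

    def _alpha_ratio(a, transition):
        before, after = transition
        key = (
            tuple(before[u] for u in a.sensor_idx + a.hidden_idx),
            tuple(after[u] for u in a.motor_idx),
        )
        if key not in ar_cache:
            ar_cache[key] = alpha_ratio_hidden(a, transition)
        return ar_cache[key]

    record("alpha_ratio_hidden", lambda: causal.state_average(
        _alpha_ratio, agent, trace, on="transitions"))

    # dynamical -----------------------------------------------------------
    record("uniqueT", lambda: dynamics.unique_transitions(trace))
    record("nLZ_space", lambda: dynamics.nlz_trace(
        trace, "space", n_permutations=config.n_permutations, seed=config.seed).value)
    record("nLZ_time", lambda: dynamics.nlz_trace(
        trace, "time", n_permutations=config.n_permutations, seed=config.seed).value)
    if deterministic:
        record("nLZ_tr_space", lambda: dynamics.nlz_transients(
            agent, "space", n_permutations=config.n_permutations, seed=config.seed).value)
        record("nLZ_tr_time", lambda: dynamics.nlz_transients(
            agent, "time", n_permutations=config.n_permutations, seed=config.seed).value)
        record("avTL", lambda: dynamics.transient_lengths(agent)[0])
        record("mTL", lambda: dynamics.transient_lengths(agent)[1])
    else:
        for name in ("nLZ_tr_space", "nLZ_tr_time", "avTL", "mTL"):
            if name in config.measures:
                missing[name] = "perturbational transients need a deterministic agent"

    return MeasurePanel(
        agent_id=agent_id,
        values=values,
        missing=missing,
        config={"m": config.m, "d": config.d,
                "n_permutations": config.n_permutations, "seed": config.seed},
        runtimes=runtimes,
    )


def correlation_matrix(panels) -> tuple:
    """Pairwise-complete Pearson correlations between panel measures.

    Returns ``(r, p)`` DataFrames (symmetric, unit diagonal).  Pairs
    with fewer than three complete observations or a constant column
    yield NaN.
    """
    panels = list(panels)
    if len(panels) < 3:
        raise ValueError("need at least three panels")
    df = pd.DataFrame([p.as_series() for p in panels])
    cols = df.columns
    r = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    p = pd.DataFrame(np.zeros((len(cols), len(cols))), index=cols, columns=cols)
    for i, a in enumerate(cols):
        for j, b in enumerate(cols):
            if j <= i:
                continue
            sub = df[[a, b]].dropna()
            if len(sub) < 3 or sub[a].nunique() < 2 or sub[b].nunique() < 2:
                rij, pij = math.nan, math.nan
            else:
                rij, pij = stats.pearsonr(sub[a], sub[b])
            r.loc[a, b] = r.loc[b, a] = rij
            p.loc[a, b] = p.loc[b, a] = pij
    return r, p
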