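"""Graph measures: LSCC/LWCC, centralities, flow hierarchy."""

import math

import numpy as np
import pytest

from autonomy.agent import Agent, classify_functional_nodes
from autonomy.structural import (
    centralities,
    flow_hierarchy,
    functional_graph,
    lscc_size,
    lwcc_size,
)
from autonomy.synthetic import AgentSpec, make_random_agent, make_reactive_agent


def agent_from_cm(n_sensors, n_hidden, n_motors, edges):
    """Agent with a given wiring; gate tables are identity-ish copies
    (structural measures only read the cm)."""
    n = n_sensors + n_hidden + n_motors
    cm = np.zeros((n, n), dtype=int)
    for i, j in edges:
        cm[i, j] = 1
    tpm = np.zeros((1 << n, n))
    states = np.arange(1 << n)
    for j in range(n_sensors, n):
        srcs = [i for i in range(n) if cm[i, j]]
        if srcs:  # OR of inputs keeps every declared edge functional
            col = np.zeros(1 << n, dtype=bool)
            for s in srcs:
                col |= ((states >> s) & 1).astype(bool)
            tpm[:, j] = col.astype(float)
    return Agent(n_sensors, n_hidden, n_motors, tpm, cm)


def test_chain_all_functional():
    agent = agent_from_cm(1, 1, 1, [(0, 1), (1, 2)])
    cls = classify_functional_nodes(agent)
    assert cls == {"sensors": (0,), "hidden": (1,), "motors": (2,), "cN": 3}
    assert lwcc_size(agent) == 3


def test_unconnected_sensor_and_sink_hidden_excluded():
    # sensor 1 has no out-edges; hidden 3 receives input but outputs nowhere
    agent = agent_from_cm(2, 2, 1, [(0, 2), (2, 4), (0, 3)])
    cls = classify_functional_nodes(agent)
    assert cls["sensors"] == (0,)
    assert cls["hidden"] == (2,)
    assert 3 not in cls["hidden"]


def test_lscc_convention():
    # recurrent pair -> 2; self-loop only -> 1; feed-forward -> 0
    recurrent = agent_from_cm(1, 2, 1, [(0, 1), (1, 2), (2, 1), (1, 3)])
    assert lscc_size(recurrent) == 2
    selfloop = agent_from_cm(1, 1, 1, [(0, 1), (1, 1), (1, 2)])
    assert lscc_size(selfloop) == 1
    feedforward = agent_from_cm(1, 1, 1, [(0, 1), (1, 2)])
    assert lscc_size(feedforward) == 0


def test_lscc_reactive_is_zero():
    assert lscc_size(make_reactive_agent(2, 2)) == 0


def test_lscc_full_recurrent_four():
    edges = [(0, i) for i in range(1, 5)]
    edges += [(i, j) for i in range(1, 5) for j in range(1, 5) if i != j]
    edges += [(i, 5) for i in range(1, 5)]
    agent = agent_from_cm(1, 4, 1, edges)
    assert lscc_size(agent) == 4


def brute_force_lscc(cm, nodes):
    """Independent oracle: all-pairs mutual reachability by DFS."""
    def reachable(a, b):
        seen, stack = set(), [a]
        while stack:
            u = stack.pop()
            for v in nodes:
                if cm[u][v] and v not in seen:
                    seen.add(v)
                    stack.append(v)
        return b in seen

    best = 0
    for a in nodes:
        comp = [b for b in nodes if reachable(a, b) and reachable(b, a)]
        if a in comp:
            best = max(best, len(comp))
        elif cm[a][a]:
            best = max(best, 1)
    return best


def test_lscc_matches_reachability_oracle():
    rng = np.random.default_rng(0)
    for _ in range(25):
        nh = int(rng.integers(2, 5))
        edges = [(0, 1 + int(rng.integers(nh)))]
        for i in range(1, 1 + nh):
            for j in range(1, 1 + nh):
                if rng.random() < 0.35:
                    edges.append((i, j))
            if rng.random() < 0.8:
                edges.append((i, 1 + nh))
        agent = agent_from_cm(1, nh, 1, edges)
        g = functional_graph(agent)
        nodes = list(g.nodes)
        cm = {a: {b: g.has_edge(a, b) for b in nodes} for a in nodes}
        assert lscc_size(agent) == brute_force_lscc(cm, nodes)


def test_adding_edge_never_decreases_components():
    rng = np.random.default_rng(1)
    for _ in range(10):
        edges = [(0, 1), (1, 2), (2, 3), (1, 3)]
        agent = agent_from_cm(1, 2, 1, edges)
        base_lscc, base_lwcc = lscc_size(agent), lwcc_size(agent)
        extra = (int(rng.integers(1, 3)), int(rng.integers(1, 3)))
        bigger = agent_from_cm(1, 2, 1, edges + [extra])
        assert lscc_size(bigger) >= base_lscc
        assert lwcc_size(bigger) >= base_lwcc


def test_two_disjoint_modules_lwcc():
    agent = agent_from_cm(2, 2, 2, [(0, 2), (2, 4), (1, 3), (3, 5)])
    assert lwcc_size(agent) == 3  # each module S->H->M has three units


def test_empty_functional_graph():
    agent = agent_from_cm(1, 1, 1, [])
    assert lwcc_size(agent) == 0
    assert lscc_size(agent) == 0
    assert math.isnan(flow_hierarchy(agent))


def test_flow_hierarchy_dag_is_one():
    rng = np.random.default_rng(2)
    for _ in range(10):
        nh = int(rng.integers(1, 4))
        hidden = list(range(1, 1 + nh))
        # chain backbone keeps every unit functional; extras stay forward-only
        edges = [(0, hidden[0])] + list(zip(hidden, hidden[1:]))
        for a in range(len(hidden) - 1):
            for b in range(a + 1, len(hidden)):
                if rng.random() < 0.6:
                    edges.append((hidden[a], hidden[b]))
        edges.append((hidden[-1], 1 + nh))
        agent = agent_from_cm(1, nh, 1, edges)
        assert flow_hierarchy(agent) == 1.0


def test_flow_hierarchy_two_cycle_zero():
    agent = agent_from_cm(0, 2, 0, [(0, 1), (1, 0)])
    assert flow_hierarchy(agent) == 0.0


def test_flow_hierarchy_dag_plus_self_loop():
    # 5 edges, one of which is a self-loop: 4/5 remain acyclic
    agent = agent_from_cm(1, 2, 1, [(0, 1), (0, 2), (1, 2), (2, 2), (2, 3)])
    assert flow_hierarchy(agent) == pytest.approx(4 / 5)


def test_degree_centrality_star():
    # hidden center fed by 3 sensors, feeding 1 motor: degree 4 over n-1=4
    agent = agent_from_cm(3, 1, 1, [(0, 3), (1, 3), (2, 3), (3, 4)])
    g = functional_graph(agent)
    import networkx as nx
    assert nx.degree_centrality(g)[3] == pytest.approx(1.0)


def test_betweenness_single_bridge_hidden():
    # every S->M path passes through the single hidden unit
    agent = agent_from_cm(2, 1, 2, [(0, 2), (1, 2), (2, 3), (2, 4)])
    _, btw = centralities(agent)
    assert btw == pytest.approx(4 / 12)  # 4 S->M pairs of 12 ordered pairs


def test_isolated_pair_degree():
    agent = agent_from_cm(1, 0, 1, [(0, 1)])
    deg, btw = centralities(agent)
    assert deg == pytest.approx(1.0)  # 2 nodes: each has degree 1 over n-1=1
    assert math.isnan(btw)  # no functional hidden units


def test_random_agents_flow_hierarchy_range(random_agents):
    for agent in random_agents:
        fh = flow_hierarchy(agent)
        if not math.isnan(fh):
            assert 0.0 <= fh <= 1.0
        cls = classify_functional_nodes(agent)
        assert lscc_size(agent) <= len(cls["hidden"]) or lscc_size(agent) <= agent.n_hidden
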