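"""Graph-theoretic measures on the agent's connectivity matrix.

All measures operate on the *functional* subgraph: units that do not
meet the functional criteria (sensors must output, motors must receive
input, hidden units must both receive from and send to another unit)
are removed first.  Graphs are directed; self-loops are meaningful and
count as cycles.
"""

from __future__ import annotations

import math

import networkx as nx
import numpy as np

from .agent import Agent, classify_functional_nodes

__all__ = [
    "functional_graph",
    "lscc_size",
    "lwcc_size",
    "centralities",
    "flow_hierarchy",
    "structural_panel",
]


def functional_graph(agent: Agent) -> nx.DiGraph:
    """Directed graph over functional units only (cm-induced subgraph)."""
    cls = classify_functional_nodes(agent)
    nodes = list(cls["sensors"] + cls["hidden"] + cls["motors"])
    g = nx.DiGraph()
    g.add_nodes_from(nodes)
    for i in nodes:
        for j in nodes:
            if agent.cm[i, j]:
                g.add_edge(i, j)
    return g


def lscc_size(agent: Agent) -> int:
    """Size of the largest strongly connected component.

    A singleton counts only if it carries a self-loop; a purely
    feed-forward graph without self-loops therefore scores 0.  Only
    hidden units can participate (sensors have no in-edges, motors no
    out-edges), so the value is bounded by ``n_hidden``.
    """
    g = functional_graph(agent)
    best = 0
    for comp in nx.strongly_connected_components(g):
        if len(comp) == 1:
            (node,) = comp
            size = 1 if g.has_edge(node, node) else 0
        else:
            size = len(comp)
        best = max(best, size)
    return best


def lwcc_size(agent: Agent) -> int:
    """Size of the largest weakly connected component of the functional graph."""
    g = functional_graph(agent)
    if g.number_of_nodes() == 0:
        return 0
    return max(len(c) for c in nx.weakly_connected_components(g))


def centralities(agent: Agent) -> tuple:
    """(mean degree centrality, mean betweenness of functional hidden units).

    Degree centrality is averaged over all functional units (in+out
    degree over n-1); betweenness (pair-normalized fraction of all-pairs
    shortest paths through a node) is averaged over functional hidden
    units only.  Undefined values are returned as NaN, not zero.
    """
    g = functional_graph(agent)
    cls = classify_functional_nodes(agent)
    if g.number_of_nodes() < 2:
        mean_degree = math.nan
    else:
        mean_degree = float(np.mean(list(nx.degree_centrality(g).values())))
    if not cls["hidden"]:
        mean_betweenness = math.nan
    else:
        bc = nx.betweenness_centrality(g, normalized=True)
        mean_betweenness = float(np.mean([bc[h] for h in cls["hidden"]]))
    return mean_degree, mean_betweenness


def flow_hierarchy(agent: Agent) -> float:
    """Fraction of functional-graph edges not participating in any cycle.

    An edge lies on a cycle iff both endpoints belong to the same
    strongly connected component (self-loops count as cycles).  NaN for
    a graph without edges.
    """
    g = functional_graph(agent)
    if g.number_of_edges() == 0:
        return math.nan
    scc_id = {}
    for k, comp in enumerate(nx.strongly_connected_components(g)):
        for node in comp:
            scc_id[node] = k
    cyclic = sum(1 for u, v in g.edges if scc_id[u] == scc_id[v])
    return 1.0 - cyclic / g.number_of_edges()


def structural_panel(agent: Agent) -> dict:
    """All structural measures for one agent."""
    cls = classify_functional_nodes(agent)
    deg, btw = centralities(agent)
    return {
        "cN": cls["cN"],
        "connected_sensors": len(cls["sensors"]),
        "connected_hidden": len(cls["hidden"]),
        "connected_motors": len(cls["motors"]),
        "len_LSCC": lscc_size(agent),
        "len_LWCC": lwcc_size(agent),
        "deg_centrality": deg,
        "betw_centrality": btw,
        "flow_hierarchy": flow_hierarchy(agent),
    }
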