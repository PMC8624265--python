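"""Shared fixtures: synthetic agents, traces, and the frozen IIT oracle."""

import json
from pathlib import Path

import numpy as np
import pytest

from autonomy.synthetic import (
    AgentSpec,
    latch_drive,
    make_latch_agent,
    make_na_solver_agent,
    make_permutation_system,
    make_random_agent,
    make_reactive_agent,
    random_drive,
)

DATA = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def reactive_agent():
    return make_reactive_agent(4, 3)


@pytest.fixture(scope="session")
def latch_agent():
    return make_latch_agent()


@pytest.fixture(scope="session")
def solver_agent():
    return make_na_solver_agent()


@pytest.fixture(scope="session")
def swap_system():
    """Closed 2-unit system whose map swaps the two state bits."""
    return make_permutation_system(2, permutation=[0, 2, 1, 3])


@pytest.fixture(scope="session")
def latch_trace(latch_agent):
    """Balanced associative-memory drive: exactly equal association counts."""
    return latch_drive(latch_agent, n_trials=100, n_steps=20, seed=7, balanced=True)


@pytest.fixture(scope="session")
def reactive_trace(reactive_agent):
    return random_drive(reactive_agent, n_trials=10, n_steps=50, seed=3)


@pytest.fixture(scope="session")
def random_agents():
    """A handful of seeded random deterministic agents of mixed archetypes."""
    specs = [
        AgentSpec("random", 3, 2, 2, seed=1),
        AgentSpec("random", 2, 3, 2, seed=2),
        AgentSpec("recurrent-pair", 2, 2, 2, seed=3),
        AgentSpec("feedforward-chain", 2, 2, 1, seed=4),
        AgentSpec("random", 4, 4, 3, seed=11),
    ]
    return [make_random_agent(s) for s in specs]


@pytest.fixture(scope="session")
def pyphi_reference():
    """Frozen reference values from the published IIT-3.0 implementation."""
    with open(DATA / "pyphi_reference.json") as fh:
        return json.load(fh)


@pytest.fixture(scope="session")
def iit_oracle_comparison(pyphi_reference):
    """Compare this package's IIT measures against the frozen oracle.

    Computed once per session; returns a dict of mismatch records that
    several tests (mechanism phi, sum phi, big Phi) assert on.
    """
    from autonomy.iit import CandidateSystem, big_phi

    mismatches = {"mechanism_phi": [], "sum_phi": [], "big_phi": []}
    n_mech_checked = n_phi_checked = 0
    cases = list(pyphi_reference["closed"]) + [
        dict(
            n=c["ns"] + c["nh"] + c["nm"],
            tpm=c["tpm"], cm=c["cm"], state=c["state_whole"],
            mechanism_phis=c["mechanism_phis"], sum_phi=c["sum_phi"],
            subset_big_phis={}, max_big_phi=None,
        )
        for c in pyphi_reference["agent_like"]
    ]
    for idx, case in enumerate(cases):
        tpm = np.array(case["tpm"], dtype=float)
        cm = np.array(case["cm"])
        state = tuple(case["state"])
        system = CandidateSystem(tpm, cm, state, tuple(range(case["n"])))
        mine = {
            ",".join(map(str, c.mechanism)): round(c.phi, 6)
            for c in system.ces()
        }
        theirs = case["mechanism_phis"]
        for key in set(mine) | set(theirs):
            n_mech_checked += 1
            a, b = mine.get(key, 0.0), theirs.get(key, 0.0)
            if abs(a - b) > 1e-6:
                mismatches["mechanism_phi"].append((idx, key, a, b))
        if abs(round(sum(mine.values()), 6) - case["sum_phi"]) > 1e-6:
            mismatches["sum_phi"].append((idx, sum(mine.values()), case["sum_phi"]))
        for key, target in case["subset_big_phis"].items():
            subset = tuple(int(x) for x in key.split(","))
            phi = round(big_phi(tpm, cm, state, subset)[0], 6)
            n_phi_checked += 1
            expected = 0.0 if target is None else target  # unreachable state
            if abs(phi - expected) > 1e-6:
                mismatches["big_phi"].append((idx, key, phi, expected))
    # big Phi of the agent-like cases, hidden subsets with sensor background
    for idx, case in enumerate(pyphi_reference["agent_like"]):
        tpm = np.array(case["tpm"], dtype=float)
        cm = np.array(case["cm"])
        state = tuple(case["state_mc"])
        for key, target in case["hidden_subset_phis"].items():
            subset = tuple(int(x) for x in key.split(","))
            phi = round(big_phi(tpm, cm, state, subset)[0], 6)
            n_phi_checked += 1
            expected = 0.0 if target is None else target
            if abs(phi - expected) > 1e-6:
                mismatches["big_phi"].append(("agent", idx, key, phi, expected))
    mismatches["n_systems"] = len(cases)
    mismatches["n_mechanism_checks"] = n_mech_checked
    mismatches["n_big_phi_checks"] = n_phi_checked
    return mismatches
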