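"""Actual causation: brute-force oracle, frozen reference, attribution."""

import math
from itertools import combinations, product

import numpy as np
import pytest

from autonomy.actual_causation import actual_cause, alpha_ratio_hidden, causal_account
from autonomy.agent import Agent
from autonomy.iit import EPSILON
from autonomy.synthetic import build_agent_from_gates, make_reactive_agent


# -- independent exhaustive oracle ------------------------------------------

def oracle_alpha(tpm, n, before, after, occ_units, x_units):
    """Direct enumeration of Eq.-style causal strength, sharing no code
    with the implementation: interventional likelihoods by averaging the
    TPM over unconstrained units, Bayes with a uniform prior, exhaustive
    partitions of the link."""

    def likelihood(occ, x_set, x_state):
        # product of per-unit marginalized factors (virtual elements):
        # each occurrence unit's probability is averaged over the
        # unconstrained units independently
        out = 1.0
        for u in occ:
            tot, cnt = 0.0, 0
            for v in range(1 << n):
                if any(((v >> uu) & 1) != s for uu, s in zip(x_set, x_state)):
                    continue
                p1 = tpm[v][u]
                tot += p1 if after[u] else 1.0 - p1
                cnt += 1
            out *= tot / cnt
        return out

    def cause_prob(occ, x_set, x_state):
        if not x_set:
            return 1.0
        num = likelihood(occ, x_set, x_state)
        den = sum(
            likelihood(occ, x_set, xs)
            for xs in product((0, 1), repeat=len(x_set))
        )
        return num / den if den else 0.0

    x_state = tuple(before[u] for u in x_units)
    p = cause_prob(occ_units, x_units, x_state)
    if p == 0:
        return 0.0
    best = math.inf
    for occ_mask in range(1 << len(occ_units)):
        for x_mask in range(1 << len(x_units)):
            n0 = tuple(u for i, u in enumerate(occ_units) if (occ_mask >> i) & 1)
            n1 = tuple(u for i, u in enumerate(occ_units) if not (occ_mask >> i) & 1)
            d0 = tuple(u for i, u in enumerate(x_units) if (x_mask >> i) & 1)
            d1 = tuple(u for i, u in enumerate(x_units) if not (x_mask >> i) & 1)
            if not ((n0 or d0) and (n1 or d1)):
                continue
            part = 1.0
            for nk, dk in ((n0, d0), (n1, d1)):
                if dk:
                    part *= cause_prob(nk, dk, tuple(before[u] for u in dk))
            if part == 0:
                continue
            a = math.log2(p / part)
            if a <= EPSILON:
                return 0.0
            best = min(best, a)
    return 0.0 if math.isinf(best) else best


def oracle_actual_cause(tpm, n, before, after, occ_units):
    best_alpha, best_x = 0.0, ()
    for k in range(1, n + 1):
        for x_units in combinations(range(n), k):
            a = oracle_alpha(tpm, n, before, after, occ_units, x_units)
            if a > best_alpha + EPSILON or (
                abs(a - best_alpha) <= EPSILON and a > EPSILON
                and len(x_units) > len(best_x)
            ):
                best_alpha, best_x = a, x_units
    return best_alpha, best_x


def test_alpha_matches_exhaustive_oracle_on_3_unit_systems(pyphi_reference):
    for case in pyphi_reference["actual_causation"][:5]:
        n = case["n"]
        tpm = case["tpm"]
        agent = Agent(0, n, 0, np.array(tpm, float), np.array(case["cm"]))
        transition = (tuple(case["before"]), tuple(case["after"]))
        for k in (1, 2, 3):
            for occ in combinations(range(n), k):
                mine = actual_cause(agent, transition, occ,
                                    cause_scope=tuple(range(n)))
                expect_alpha, expect_x = oracle_actual_cause(
                    tpm, n, transition[0], transition[1], occ)
                assert mine.alpha == pytest.approx(expect_alpha, abs=1e-9)
                if expect_alpha > EPSILON:
                    assert mine.cause_units == expect_x


def test_alpha_matches_frozen_reference(pyphi_reference):
    for case in pyphi_reference["actual_causation"]:
        n = case["n"]
        agent = Agent(0, n, 0, np.array(case["tpm"], float), np.array(case["cm"]))
        transition = (tuple(case["before"]), tuple(case["after"]))
        for key, rec in case["occurrences"].items():
            occ = tuple(int(x) for x in key.split(","))
            mine = actual_cause(agent, transition, occ,
                                cause_scope=tuple(range(n)))
            assert mine.alpha == pytest.approx(rec["alpha"], abs=1e-6)
            if rec["cause"]:
                assert list(mine.cause_units) == rec["cause"]


def test_binary_copy_alpha_one_bit():
    # B copies A; occurrence (B=1) after (A=1): alpha = 1 bit, cause (A=1)
    tpm = np.zeros((4, 2))
    tpm[:, 1] = [0, 1, 0, 1]
    agent = Agent(0, 2, 0, tpm, np.array([[0, 1], [0, 0]]))
    occ = actual_cause(agent, ((1, 0), (0, 1)), (1,), cause_scope=(0,))
    assert occ.alpha == pytest.approx(1.0, abs=1e-12)
    assert occ.cause_units == (0,)
    assert occ.cause_state == (1,)


def test_occurrence_independent_of_past_has_no_cause():
    tpm = np.zeros((4, 2))
    tpm[:, 1] = 1.0  # B is constant-on regardless of the past
    agent = Agent(0, 2, 0, tpm, np.zeros((2, 2), dtype=int))
    occ = actual_cause(agent, ((0, 0), (0, 1)), (1,), cause_scope=(0, 1))
    assert occ.alpha == 0.0
    assert occ.cause_units == ()


def test_inconsistent_transition_rejected():
    tpm = np.zeros((4, 2))
    tpm[:, 1] = [0, 1, 0, 1]
    agent = Agent(0, 2, 0, tpm, np.array([[0, 1], [0, 0]]))
    with pytest.raises(ValueError, match="inconsistent"):
        actual_cause(agent, ((0, 0), (0, 1)), (1,), cause_scope=(0,))


# -- Shapley attribution -----------------------------------------------------

def test_shapley_efficiency(pyphi_reference):
    case = pyphi_reference["actual_causation"][1]
    n = case["n"]
    agent = Agent(0, n, 1, _pad_motor(case["tpm"], n), _pad_cm(case["cm"], n))
    # attach a motor copying unit 0 so the account has a motor occurrence
    transition = _padded_transition(agent, case["before"])
    account = causal_account(agent, transition, cause_scope=tuple(range(n)))
    for occ in account.occurrences:
        if occ.alpha > EPSILON:
            assert sum(occ.shapley.values()) == pytest.approx(occ.alpha, abs=1e-10)


def _pad_motor(tpm, n):
    """Extend a closed n-unit tpm with one motor unit copying unit 0."""
    full = np.zeros((1 << (n + 1), n + 1))
    for v in range(1 << (n + 1)):
        base = v & ((1 << n) - 1)
        full[v, :n] = tpm[base]
        full[v, n] = base & 1
    return full


def _pad_cm(cm, n):
    full = np.zeros((n + 1, n + 1), dtype=int)
    full[:n, :n] = cm
    full[0, n] = 1
    return full


def _padded_transition(agent, before):
    b = tuple(before) + (0,)
    row = sum(bit << i for i, bit in enumerate(b))
    after = tuple(int(x) for x in agent.tpm[row])
    return b, after


def test_alpha_ratio_sensor_driven_motors_zero():
    agent = make_reactive_agent(2, 2)
    before = (1, 0, 0, 0)
    after = (0, 0, 1, 0)  # motors copy previous sensors
    assert alpha_ratio_hidden(agent, (before, after)) == pytest.approx(0.0)


def test_alpha_ratio_hidden_driven_motors_one():
    # motor copies the hidden unit; hidden copies itself
    agent = build_agent_from_gates(
        1, 1, 1, {1: ((1,), np.array([0.0, 1.0])),
                  2: ((1,), np.array([0.0, 1.0]))})
    before = (0, 1, 0)
    after = (0, 1, 1)
    assert alpha_ratio_hidden(agent, (before, after)) == pytest.approx(1.0)


def test_alpha_ratio_mixed_cause_is_half():
    # motor = sensor AND hidden: the two units contribute symmetrically,
    # so each receives half the causal strength by Shapley symmetry
    agent = build_agent_from_gates(
        1, 1, 1, {1: ((1,), np.array([0.0, 1.0])),
                  2: ((0, 1), np.array([0.0, 0.0, 0.0, 1.0]))})
    before = (1, 1, 0)
    after = (0, 1, 1)
    ratio = alpha_ratio_hidden(agent, (before, after))
    assert 0.0 < ratio < 1.0
    assert ratio == pytest.approx(0.5, abs=1e-9)


def test_alpha_ratio_nan_when_no_causes():
    # motors constant: no occurrence has a cause
    agent = build_agent_from_gates(
        1, 1, 1, {1: ((1,), np.array([0.0, 1.0]))})
    before = (0, 0, 0)
    after = (0, 0, 0)
    assert math.isnan(alpha_ratio_hidden(agent, (before, after)))
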