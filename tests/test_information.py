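"""Observational information measures against brute-force oracles.

The oracles here recompute each quantity directly from joint frequency
tables built with plain dictionaries over the pooled samples, sharing
no code with the implementation under test.
"""

import math
from collections import Counter
from itertools import combinations

import numpy as np
import pytest

from autonomy.information import (
    autonomy_A,
    information_closure_J,
    multi_information,
    ntic,
    predictive_information,
    sensor_motor_mi,
    system_entropy,
    tse_complexity,
)
from autonomy.synthetic import build_agent_from_gates, latch_drive, random_drive
from autonomy.trace import ActivityTrace, EmpiricalDistribution, entropy


# -- oracle helpers --------------------------------------------------------

def oracle_H(samples):
    counts = Counter(samples)
    n = sum(counts.values())
    return -sum((c / n) * math.log2(c / n) for c in counts.values())


def pooled(trace, extractor, max_lag):
    out = []
    for trial in trace.trials:
        for t in range(max_lag, len(trial)):
            out.append(extractor(trial, t))
    return out


# -- entropy ---------------------------------------------------------------

def test_entropy_examples():
    assert entropy([0.25] * 4) == pytest.approx(2.0)
    assert entropy([1.0, 0.0]) == pytest.approx(0.0)
    assert entropy([0.5, 0.25, 0.25]) == pytest.approx(1.5)


def test_entropy_rejects_unnormalized():
    with pytest.raises(ValueError):
        entropy([0.5, 0.4])


def test_empirical_distribution_from_samples():
    samples = np.array([[0], [0], [1], [2]])
    dist = EmpiricalDistribution.from_samples(samples)
    assert dist.entropy() == pytest.approx(1.5)


# -- sensor-motor mutual information ----------------------------------------

@pytest.fixture(scope="module")
def copy_agent():
    """1 sensor, 1 motor; motor copies the sensor with one step delay."""
    return build_agent_from_gates(1, 0, 1, {1: ((0,), np.array([0.0, 1.0]))})


def test_smmi_copy_is_one_bit(copy_agent):
    trace = random_drive(copy_agent, n_trials=4, n_steps=400, seed=0)
    # the motor is an exact copy, so I(S;M) equals the empirical sensor
    # entropy (close to, but not exactly, 1 bit for sampled drive)
    h_s = oracle_H(pooled(trace, lambda tr, t: tr[t - 1][0], 1))
    assert sensor_motor_mi(trace, copy_agent, d=1) == pytest.approx(h_s, abs=1e-12)
    assert sensor_motor_mi(trace, copy_agent, d=1) == pytest.approx(1.0, abs=0.01)


def test_smmi_independent_is_zero(copy_agent):
    rng = np.random.default_rng(0)
    trials = [rng.integers(0, 2, (300, 2)).astype(np.uint8) for _ in range(3)]
    trace = ActivityTrace(trials)
    mi = sensor_motor_mi(trace, copy_agent, d=1)
    assert 0.0 <= mi < 0.02


def test_smmi_bounded_by_motor_entropy(latch_agent, latch_trace):
    h_m = oracle_H(pooled(latch_trace, lambda tr, t: tuple(tr[t][5:]), 1))
    for d in (1, 2, 3):
        assert sensor_motor_mi(latch_trace, latch_agent, d=d) <= h_m + 1e-12


def test_smmi_matches_joint_count_oracle(latch_agent, latch_trace):
    samples = pooled(latch_trace, lambda tr, t: (tuple(tr[t - 1][:4]),
                                                 tuple(tr[t][5:])), 1)
    h_s = oracle_H([s for s, _ in samples])
    h_m = oracle_H([m for _, m in samples])
    h_sm = oracle_H(samples)
    assert sensor_motor_mi(latch_trace, latch_agent, 1) == pytest.approx(
        h_s + h_m - h_sm, abs=1e-10)


# -- predictive information --------------------------------------------------

def test_ipred_deterministic_cycle():
    # (O,M) cycles through 4 distinct states -> H(V_t|V_{t-1}) = 0
    cycle = np.array(([[0, 0, 0], [0, 0, 1], [0, 1, 0], [0, 1, 1]] * 50) + [[0, 0, 0]],
                     dtype=np.uint8)  # 201 rows: lag-1 samples are exactly uniform
    trace = ActivityTrace([cycle])
    agent = build_agent_from_gates(1, 1, 1, {1: ((1,), np.array([0.0, 1.0])),
                                             2: ((1,), np.array([0.0, 1.0]))})
    assert predictive_information(trace, agent) == pytest.approx(2.0, abs=1e-9)


def test_ipred_iid_near_zero():
    rng = np.random.default_rng(1)
    trace = ActivityTrace([rng.integers(0, 2, (4000, 3)).astype(np.uint8)])
    agent = build_agent_from_gates(1, 1, 1, {1: ((1,), np.array([0.0, 1.0])),
                                             2: ((1,), np.array([0.0, 1.0]))})
    assert predictive_information(trace, agent) < 0.01


def test_ipred_matches_double_sum_oracle(latch_agent, latch_trace):
    samples = pooled(latch_trace, lambda tr, t: (tuple(tr[t - 1][4:]),
                                                 tuple(tr[t][4:])), 1)
    n = len(samples)
    joint = Counter(samples)
    pa = Counter(a for a, _ in samples)
    pb = Counter(b for _, b in samples)
    mi = sum(
        (c / n) * math.log2((c / n) / ((pa[a] / n) * (pb[b] / n)))
        for (a, b), c in joint.items()
    )
    assert predictive_information(latch_trace, latch_agent) == pytest.approx(
        mi, abs=1e-10)


# -- sensor-conditioned autonomy ---------------------------------------------

def test_autonomy_reactive_zero(reactive_agent, reactive_trace):
    for m in (1, 2, 4):
        assert autonomy_A(reactive_trace, reactive_agent, m) == pytest.approx(
            0.0, abs=1e-12)


def test_autonomy_latch_one_bit(latch_agent, latch_trace):
    assert autonomy_A(latch_trace, latch_agent, 4) == pytest.approx(1.0, abs=1e-12)


def test_autonomy_second_term_zero_for_deterministic(latch_agent, latch_trace):
    # H(OM_t | OM_{t-1}, S-window) must vanish: adding the window to the
    # full previous internal state cannot leave any uncertainty
    m = 4
    samples = pooled(
        latch_trace,
        lambda tr, t: (tuple(tr[t][4:]), tuple(tr[t - 1][4:]),
                       tuple(tuple(tr[t - lag][:4]) for lag in range(1, m + 1))),
        m,
    )
    h_cond = oracle_H(samples) - oracle_H([(om1, w) for _, om1, w in samples])
    assert h_cond == pytest.approx(0.0, abs=1e-12)


def test_autonomy_requires_positive_m(latch_trace, latch_agent):
    with pytest.raises(ValueError):
        autonomy_A(latch_trace, latch_agent, 0)


# -- information closure -----------------------------------------------------

def test_closure_sensor_ignoring_agent():
    agent = build_agent_from_gates(1, 1, 0, {1: ((1,), np.array([1.0, 0.0]))})
    trace = random_drive(agent, n_trials=2, n_steps=200, seed=2)
    assert information_closure_J(trace, agent) == pytest.approx(0.0, abs=1e-12)


def test_closure_copying_hidden_unit_is_one_bit():
    # h copies a uniform sensor bit; h's own past carries no information
    agent = build_agent_from_gates(1, 1, 0, {1: ((0,), np.array([0.0, 1.0]))})
    trace = random_drive(agent, n_trials=2, n_steps=3000, seed=3)
    assert information_closure_J(trace, agent) == pytest.approx(1.0, abs=0.01)


def test_closure_matches_conditional_mi_oracle(latch_agent, latch_trace):
    samples = pooled(latch_trace, lambda tr, t: (tuple(tr[t][4:]),
                                                 tuple(tr[t - 1][:4]),
                                                 tuple(tr[t - 1][4:])), 1)
    h_ab = oracle_H([(a, g) for a, _, g in samples])
    h_bg = oracle_H([(b, g) for _, b, g in samples])
    h_abg = oracle_H(samples)
    h_g = oracle_H([g for _, _, g in samples])
    assert information_closure_J(latch_trace, latch_agent) == pytest.approx(
        h_ab + h_bg - h_abg - h_g, abs=1e-10)


# -- non-trivial information closure -----------------------------------------

def test_ntic_identity_on_traces(latch_agent, latch_trace, reactive_agent,
                                 reactive_trace, random_agents):
    for agent, trace in [(latch_agent, latch_trace),
                         (reactive_agent, reactive_trace)]:
        lhs = ntic(trace, agent, 4)
        rhs = (predictive_information(trace, agent, burn_in=4)
               - autonomy_A(trace, agent, 4))
        assert abs(lhs - rhs) < 1e-10
    agent = random_agents[1]
    trace = random_drive(agent, n_trials=4, n_steps=100, seed=9)
    lhs = ntic(trace, agent, 4)
    rhs = (predictive_information(trace, agent, burn_in=4)
           - autonomy_A(trace, agent, 4))
    assert abs(lhs - rhs) < 1e-10


def test_ntic_zero_for_doubly_independent_system():
    # hidden constant, sensors random: system independent of both its past
    # and the sensors
    agent = build_agent_from_gates(1, 1, 0, {1: ((1,), np.array([0.0, 0.0]))})
    trace = random_drive(agent, n_trials=2, n_steps=200, seed=5)
    assert ntic(trace, agent, 2) == pytest.approx(0.0, abs=1e-12)


def test_ntic_negative_for_xor_drive():
    # h_t = h_{t-1} XOR s_{t-1}: sensors and system jointly determine the
    # next state; alone neither predicts it
    agent = build_agent_from_gates(
        1, 1, 0, {1: ((0, 1), np.array([0.0, 1.0, 1.0, 0.0]))})
    trace = random_drive(agent, n_trials=4, n_steps=2000, seed=6)
    assert ntic(trace, agent, 1) < -0.5


# -- multi-information and TSE ----------------------------------------------

def test_multi_information_independent_zero():
    rng = np.random.default_rng(7)
    trace = ActivityTrace([rng.integers(0, 2, (2000, 3)).astype(np.uint8)])
    assert multi_information(trace, [0, 1, 2]) < 0.01


def test_multi_information_perfectly_correlated():
    bits = np.random.default_rng(8).integers(0, 2, 500).astype(np.uint8)
    trace = ActivityTrace([np.column_stack([bits, bits])])
    assert multi_information(trace, [0, 1]) == pytest.approx(
        entropy(np.bincount(bits, minlength=2) / len(bits)))


def test_multi_information_matches_term_oracle(latch_agent, latch_trace):
    units = list(range(8))
    samples = pooled(latch_trace, lambda tr, t: tuple(tr[t]), 0)
    expect = sum(oracle_H([s[u] for s in samples]) for u in units) - oracle_H(samples)
    assert multi_information(latch_trace, units) == pytest.approx(expect, abs=1e-10)


def test_tse_independent_units_zero():
    rng = np.random.default_rng(9)
    trace = ActivityTrace([rng.integers(0, 2, (600, 3)).astype(np.uint8)])
    assert abs(tse_complexity(trace, [0, 1, 2])) < 0.02


def test_tse_fully_redundant_four_bits():
    bits = np.random.default_rng(10).integers(0, 2, 4000).astype(np.uint8)
    trace = ActivityTrace([np.column_stack([bits] * 4)])
    # each subset has the entropy of one near-uniform bit h:
    # C = sum_k (h - (k/4) h) = h * (3/2)
    h = entropy(np.bincount(bits, minlength=2) / len(bits))
    assert tse_complexity(trace, [0, 1, 2, 3]) == pytest.approx(1.5 * h, abs=1e-10)


def test_tse_matches_subset_enumeration_oracle():
    rng = np.random.default_rng(11)
    raw = rng.integers(0, 2, (300, 5)).astype(np.uint8)
    raw[:, 3] = raw[:, 0] ^ raw[:, 1]  # inject structure
    trace = ActivityTrace([raw])
    samples = [tuple(row) for row in raw]
    n = 5
    h_full = oracle_H(samples)
    expect = 0.0
    for k in range(1, n + 1):
        hs = [oracle_H([tuple(s[u] for u in c) for s in samples])
              for c in combinations(range(n), k)]
        expect += sum(hs) / len(hs) - (k / n) * h_full
    assert tse_complexity(trace, list(range(n))) == pytest.approx(expect, abs=1e-10)


# -- global invariants -------------------------------------------------------

def test_doubling_trace_leaves_measures_unchanged(latch_agent, latch_trace):
    doubled = latch_trace.concatenate(latch_trace)
    for fn in (lambda t: autonomy_A(t, latch_agent, 4),
               lambda t: predictive_information(t, latch_agent),
               lambda t: sensor_motor_mi(t, latch_agent, 1),
               lambda t: information_closure_J(t, latch_agent),
               lambda t: multi_information(t, list(range(8))),
               lambda t: system_entropy(t, latch_agent)):
        assert fn(doubled) == pytest.approx(fn(latch_trace), abs=1e-12)


def test_nonnegativity_invariants(random_agents):
    for agent in random_agents[:3]:
        trace = random_drive(agent, n_trials=3, n_steps=80, seed=13)
        assert autonomy_A(trace, agent, 2) >= -1e-12
        assert information_closure_J(trace, agent) >= -1e-12
        assert predictive_information(trace, agent) >= -1e-12
        assert multi_information(trace, list(range(agent.n_units))) >= -1e-12
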