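# autonomy

Quantitative measures of autonomy for small discrete automata.

How much does an artificial agent determine its own behavior, and how
much is it driven by its environment?  This package implements a panel
of candidate answers for sensor/hidden/motor automata described by
transition probability matrices (TPMs) — the "Markov Brain" style of
evolvable binary network used in artificial-life and
computational-neuroscience studies of agency, memory and integration.
It is aimed at researchers who want to compare structural,
information-theoretic, causal and dynamical notions of autonomy on the
same substrates, without committing to any single framework.

## The measures

For a system V = {S, O, M} of binary sensors, hidden units and motors
with Markovian dynamics p(v_{t+1} | v_t), the panel covers:

**Structural** (connectivity matrix): functional unit counts (cN),
largest strongly/weakly connected component (len_LSCC, len_LWCC),
mean degree and betweenness centrality, flow hierarchy.

**Informational** (observed activity, plug-in estimates, bits):

* sensor–motor mutual information  I(S_t; M_{t+d})
* predictive information           I_pred = I(OM_{t-1}; OM_t)
* sensor-conditioned autonomy      A_m^S = H(OM_t | S_{t-1..t-m})
                                          − H(OM_t | OM_{t-1}, S_{t-1..t-m})
* information flow / closure       J = I(OM_{t+1}; S_t | OM_t)
* non-trivial information closure  NTIC_m = I_pred − A_m^S
* multi-information (total correlation) and TSE complexity

**Causal** (perturbational, from the TPM under maximum-entropy
interventions): effective information EI; the interventional autonomy
Â_m^S (with Â_1^S = EI exactly); mechanism-level integrated
information φ and its sum over all mechanisms Σφ; the major complex
and its Φ (IIT 3.0: EMD repertoire distances, minimum-information
partitions, unidirectional system cuts); actual causation α_c with
exact Shapley attribution of motor causes to hidden vs. sensor units
(alpha_ratio_hidden).

**Dynamical**: unique state transitions; normalized Lempel–Ziv
complexity of recorded activity and of perturbational transients
(nLZ_space/time, nLZ_tr_space/time); average and maximum transient
length under clamped sensors.

A grid-world path-following task (45° turns cued by turn symbols,
fixed or randomly assigned per trial) and a family of synthetic agent
generators (reactive, one-bit latch, feed-forward, recurrent,
permutation-closed, random) provide everything needed to exercise and
test each measure without external data.

## Worked example

The associative-memory contrast in two lines per agent: a reactive
controller (motors copy sensors) versus a latch controller that stores
a per-trial association bit in a self-sustaining hidden unit.

```python
from autonomy import (make_latch_agent, make_reactive_agent, latch_drive,
                      random_drive, autonomy_A, predictive_information,
                      effective_information, causal_autonomy, lscc_size)

latch = make_latch_agent()
reactive = make_reactive_agent(4, 3)
trace_l = latch_drive(latch, n_trials=200, n_steps=20, seed=1)
trace_r = random_drive(reactive, n_trials=10, n_steps=50, seed=1)

for name, ag, tr in [("latch", latch, trace_l), ("reactive", reactive, trace_r)]:
    print(f"{name}: A_4^S = {autonomy_A(tr, ag, 4):.3f} bits, "
          f"I_pred = {predictive_information(tr, ag):.3f} bits, "
          f"EI = {effective_information(ag):.3f} bits, "
          f"A-hat_4^S = {causal_autonomy(ag, 4):.3f} bits, "
          f"len_LSCC = {lscc_size(ag)}")
```

prints

```
latch: A_4^S = 0.999 bits, I_pred = 0.999 bits, EI = 0.750 bits, A-hat_4^S = 0.094 bits, len_LSCC = 1
reactive: A_4^S = 0.000 bits, I_pred = 0.047 bits, EI = 0.000 bits, A-hat_4^S = 0.000 bits, len_LSCC = 0
```

The latch agent carries one bit of "autonomous" information — the
stored association, which the last four sensor states cannot explain —
while the reactive agent carries none.  Its causal self-determination
is smaller (EI = 0.75 bits; Â_4^S = 0.094 bits after four steps of
maximum-entropy sensor noise erode the latch), and its single
self-loop unit (len_LSCC = 1) is not enough for integrated information:
a major complex needs a strongly connected pair, so Φ = 0 here.

The same panel is available in one call (`compute_panel`) and from the
shell:

```bash
autonomy make-agent --archetype latch --seed 7 --out agent.json
autonomy run --agent agent.json --drive latch --seed 1 --out trace.csv
autonomy panel --agent agent.json --trace trace.csv --out panel.json
autonomy correlate --panels panels/ --out corr.csv
```

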