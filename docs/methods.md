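# Methods

This note documents the models and conventions behind the measure
panel: what each measure computes, the interventional protocols, the
numerical choices, what the synthetic agents and the grid-world task do
and do not emulate, and the design decisions taken where the underlying
definitions leave room.

## Agent model

An agent is a network of `n = n_sensors + n_hidden + n_motors` binary
units with Markovian dynamics, fully described by a state-by-node
transition probability matrix (TPM): row `v` (little-endian state
index; unit 0 is the least-significant bit) and column `i` hold
`P(unit i = 1 at t+1 | state v at t)`.  The state-by-node form is valid
because units update conditionally independently given the previous
full state; `to_state_by_state` provides the `2^n x 2^n` expansion.
Three structural constraints define the sensor/hidden/motor partition:

* sensors are written only by the environment — their TPM columns are
  stored as all-zero placeholders and no measure reads them;
* no unit inside the system writes to a sensor;
* motors act on the environment but do not feed back — hidden and
  motor columns are invariant to the motor bits of the current state.

`validate_agent` checks all invariants (including that every column is
invariant to units the connectivity matrix declares as non-inputs) and
returns the violations rather than raising, so a file can be diagnosed
in one pass.  The loader enforces the canonical unit order (sensors,
hidden, motors) instead of permuting silently.

Functional units are classified in a single pass from the connectivity
matrix: sensors must output to another unit, motors must receive
input, hidden units must receive input (a self-loop counts) and output
to *another* unit.  All structural measures operate on the functional
subgraph.

## Structural measures

`len_LSCC` is the size of the largest strongly connected component,
with the convention that a singleton counts only if it has a
self-loop: a purely feed-forward network scores 0, a feed-forward
network whose hidden units latch through self-loops scores 1, and a
recurrent hidden core scores its size.  This reconciles the two
standard readings (feed-forward nets "have LSCC zero" vs. self-loop
units forming their own component).  Flow hierarchy is the fraction of
edges not participating in any cycle, where an edge lies on a cycle
iff both endpoints share a strongly connected component (self-loops
are cycles).  Degree centrality (in+out degree over `n-1`) is averaged
over all functional units; betweenness centrality (pair-normalized,
via networkx) over functional hidden units only.  Undefined values
(no functional units, no edges, no hidden units) are NaN, never zero.

## Observational information measures

All information measures are plug-in (maximum-likelihood) estimates in
bits from pooled trial samples; there is no smoothing or bias
correction, so small samples bias conditional entropies downward — the
drive protocols below are designed so that the quantities being tested
are exact despite this.  Lag-m statistics never straddle a trial
boundary; the first m steps of each trial are dropped.  The "system"
is the hidden+motor set (O, M) with the sensors S standing in for the
environment, because the sensor state is written directly by the
environment.  A flag widens the predictive-information scope to the
full state when needed.

* `sensor_motor_mi`: I(S_t; M_{t+d}), default d = 1.
* `predictive_information`: I(V_{t-1}; V_t) with V = (O, M).
* `autonomy_A` (A_m^S): H(OM_t | S_{t-1..t-m}) −
  H(OM_t | OM_{t-1}, S_{t-1..t-m}); the subtracted term is identically
  zero for deterministic agents.  Default m = 4.
* `information_closure_J`: I(OM_{t+1}; S_t | OM_t), zero for
  informationally closed systems.
* `ntic` (NTIC_m): I(OM_t; S-window) − I(OM_t; S-window | OM_{t-1}).
  Computed from the same pooled sample set as A_m^S and I_pred so that
  the identity NTIC_m = I_pred − A_m^S holds to floating-point
  cancellation error (< 1e-10), not merely asymptotically.  NTIC can
  be negative (e.g. an XOR of sensor and hidden past).
* `multi_information` and `tse_complexity` default to all functional
  units; TSE enumerates all subsets exhaustively (n ≤ 12).

## Perturbational (causal) measures

These are computed from the TPM under maximum-entropy interventions
and are properties of the mechanism, not of the visited distribution.

**Effective information.** For closed systems, EI is the classic
uniform-perturbation quantity `|Ω|⁻¹ Σ_v D_KL(p(V_t|v) ‖ p(V_t))`,
which for deterministic maps equals the entropy of the image
distribution and reaches n bits exactly iff the map permutes the state
space.  For open agents, sensors are treated as maximum-entropy
background that is *conditioned on*:

    EI = H(OM_t | Ŝ_{t-1}) − H(OM_t | V̂_{t-1}).

This is a deliberate design choice: it makes the m = 1 causal autonomy
equal to EI exactly *and* assigns zero EI to a purely reactive agent,
both of which fail under the alternative reading in which the sensor
drive is marginalized into the output entropy (a reactive agent would
then inherit the full entropy of the sensor stream as "effective
information", which contradicts EI's role as a self-determination
measure).

**Causal autonomy** (Â_m^S).  The internal state at t−m and the sensor
states at every step t−m..t−1 are independently perturbed to maximum
entropy and the ensemble is propagated through the TPM exactly; the
reported value is H(OM_t | sensor sequence) − H(OM_t | V̂_{t-1}).  The
propagation merges sensor sequences whose internal-state distributions
have collapsed to the same value, which keeps the exact computation
tractable (the 4-sensor, m = 4 case has 65 536 sequences but far fewer
distinct distributions).  Â_1^S = EI holds at machine precision by
construction.  Stochastic agents are currently not supported by this
routine (the deterministic case is the one the panel targets).

**Integrated information (IIT 3.0).**  The `iit` module implements the
full mechanism- and system-level analysis: cause repertoires (Bayesian
inversion of per-unit factors with uniform priors, "virtual element"
products), effect repertoires (products of clamped-mechanism Bernoulli
factors), small phi as the earth-mover's distance between the intact
repertoire and the minimum-information bipartition of (mechanism,
purview), concepts (min of cause and effect phi), and big Phi as the
minimal concept-space distance between the intact cause-effect
structure and that of the system under any unidirectional cut.
Conventions follow the published IIT 3.0 account precisely:

* EMD with Hamming ground metric on the cause side (solved exactly as
  a support-restricted transportation LP via HiGHS); on the effect
  side repertoires factorize and the EMD reduces to the summed
  per-unit marginal shifts;
* mechanism partitions are the standard bipartitions (empty parts
  allowed, the fully trivial split excluded); purview ties prefer
  larger purviews, then the earliest in size-ascending enumeration;
* system cuts sever the connections from one part to the rest and
  replace them with independent noise; the cut cause-effect structure
  is evaluated over the original concepts' mechanisms plus all
  mechanisms the cut splits;
* the concept-space distance moves disappearing concepts to the null
  concept (unconstrained repertoires) and otherwise solves the
  extended EMD over unmatched concepts, with the phi surplus assigned
  to the null concept on the lighter side;
* units outside the candidate system are background conditions frozen
  in their current state; candidates whose joint state is unreachable
  given those conditions have no cause repertoires and cannot form
  complexes;
* a single unit, a candidate that is not strongly connected, or an
  empty cause-effect structure yields Phi = 0, so Phi = 0 whenever the
  hidden LSCC is smaller than 2;
* values are reported to six decimals (the reference implementation's
  printing precision).

Agreement with the published reference implementation (pyphi 1.2.0,
default EMD configuration) was verified on a frozen corpus of seeded
random deterministic systems — mechanism phi, sum of phi, and big Phi
for every candidate subset — stored as a text fixture under
`tests/data/`; the test suite recomputes all of it on every run.

`sum_phi_whole` evaluates the whole network (sensors and motors
included as candidate units).  Mechanisms containing a unit with no
inputs or no outputs within the candidate system are exactly reducible
(the partition that splits that unit off changes nothing) and are
pruned without changing any value; in practice this leaves the hidden
mechanisms.  `major_complex` searches all non-empty hidden subsets —
sensors feed in and motors read out in a feed-forward manner, so only
hidden units can be strongly connected.

**Actual causation.**  For an observed transition v_{t-1} ≺ v_t and an
occurrence y_t (a subset of units in its time-t state), the causal
strength alpha_c of a candidate cause x_{t-1} is the minimal-partition
log-ratio of the interventional probability of x_{t-1} given y_t (the
occurrence's cause repertoire evaluated at the candidate's state) to
the same probability under the partitioned link; partitions that give
zero or negative irreducibility make alpha_c zero.  The actual cause
maximizes alpha_c; ties prefer larger candidate sets.  Candidate
causes range over the functional sensors and hidden units (motors
cannot cause anything), and candidates containing units with no
connection to the occurrence are exactly reducible and skipped.

The hidden-cause ratio treats the account compositionally: every
non-empty subset of the motor state is an occurrence; alpha_c is
attributed to the units of its actual cause by exact Shapley values
with coalition value v(T) = alpha_c of the link from sub-coalition T
(in its observed state) to the occurrence, so efficiency guarantees
the values sum to alpha_c.  The reported measure is the ratio of the
summed hidden-unit Shapley mass to the summed alpha_c over
occurrences: 1 when motors are caused from within, 0 when caused by
the sensors alone, NaN when nothing has a cause.  The ratio (rather
than an alpha-weighted sum) is the reading consistent with its role as
a *relative* contribution bounded by [0, 1].

**State averaging.**  All IIT quantities are state-dependent; per-agent
values average them over the observed states (or transitions) of a
trace, weighted by visit frequency.  NaN values are excluded with
renormalized weights.  The panel memoizes per distinct
(sensor, hidden) substate — motor bits feed nothing back, and for the
whole-network sum of phi only mechanism (hidden) states matter — which
bounds the number of expensive evaluations regardless of trace length.

## Dynamical measures

`lz76_complexity` implements the exhaustive-history parsing
(Kaspar–Schuster scan; JIT-compiled via numba when available, with a
pure-Python fallback).  `nlz` normalizes by the mean complexity of 100
seeded uniform permutations of the symbol positions; an all-constant
string has an uninformative baseline and is flagged degenerate rather
than suppressed.  Activity is flattened time-major ("space": each
step's unit vector concatenated) or unit-major ("time") before
parsing; multi-trial traces are concatenated into one string for nlz
but respect trial boundaries for `unique_transitions`.

Perturbational transients iterate the sensor-conditioned deterministic
map from every (hidden, motor) state for every fixed sensor state; the
transient length counts the steps strictly before the first revisited
state, which covers fixed points and limit cycles uniformly (a state
on its attractor has transient length 0).  `nlz_transients`
concatenates all trajectories in a fixed order (sensor index
ascending, then start state ascending).  All sensor states are
enumerated; per-sensor-state values are available from the transient
set itself.

## Synthetic agents and drive protocols

The generators produce the study conditions for every measure without
external data.  The *reactive* agent (motors a deterministic function
of current sensors, no hidden units) and the *latch* agent (one
self-sustaining hidden unit that copies the turn-symbol sensor on a
cue, motors a function of hidden and location sensors) emulate the two
poles of the associative-memory contrast: a controller for the
fixed-symbol condition needs no memory, a controller for the
random-symbol condition must store the per-trial association.

`latch_drive` is the corresponding recording protocol: each trial
draws an association bit, presents it once through the cue sensors in
a warm-up step that precedes the recorded activity, then feeds neutral
on-path input.  Starting the recording after storage means no recorded
lag-4 sensor window straddles the cue, so the pooled A_4^S equals the
entropy of the association bit exactly — 1.0 bit for balanced
associations, ≈ 0.999 bits for 200 uniformly drawn trials.  (If the
cue step were recorded, the one window per trial that reaches back to
it would reveal the bit and bias A_4^S to (T−m−1)/(T−m) bits.)
Defaults are 200 trials of 20 recorded steps.

These synthetic traces are deliberately minimal: they do not emulate
the closed sensorimotor loop (sensor input is open-loop), evolved
redundancy, or behavioral diversity of real evolved agents.  Passing
tests on them shows the measures compute their defining quantities
correctly, not that any particular value will be observed in evolved
populations.

## Path-following environment

The grid world rewards visiting the cells of a predefined path with
45-degree turns marked by turn-symbol cells.  Motor decoding follows
the fixed table (000 no movement, 100 left, 010 right, 110 forward,
XX1 reverse); left/right rotate the 8-direction heading by 45 degrees
in place, forward/reverse translate one cell (diagonals included).
Location sensors are a strict one-hot (on-path / off-path / on-turn);
symbol bits read the current cell's code and are zero off turn cells.
Fixed-symbol worlds use 0 = left, 1 = right; randomized worlds redraw
an injective direction→code assignment per trial (1 bit: swap; 2 bits:
two distinct codes of four).  Fitness is the number of distinct
non-start path cells visited, plus the remaining steps if the goal is
reached before the time-out (path length + 50), minus 0.25 per step on
empty cells; moves off the grid clamp to the border and count as
off-path steps.  The start cell does not count as visited (an agent
that never moves scores exactly 0).  Four bundled maps (plus mirrored
versions with left/right roles exchanged) are repo-designed
illustrations, not reproductions of any particular published map set;
start heading points toward the second path cell, and turning consumes
a time step.

## Numerical conventions

Logarithms are base 2 everywhere; 0·log 0 = 0.  Probability tables are
validated to sum to 1 within 1e-12.  IIT values are rounded to 1e-6;
small-phi concepts below 1e-6 are excluded from cause-effect
structures.  EMD transportation problems are solved exactly on the
joint support; a cheap lower bound (max of total variation and summed
per-bit marginal shifts) prunes partitions that cannot affect the
minimum, and purview searches abort as soon as their running minimum
falls below the best purview so far — both prunings are exact.  Seeds
are explicit arguments everywhere; no global random state is used.

## Known limitations

* Exhaustive enumerations (TSE subsets, IIT purviews and partitions,
  Shapley coalitions) limit practical system sizes to ~12 units,
  matching the intended domain of small evolved automata.
* Plug-in estimation makes the observational measures biased for
  short traces; no correction is applied.
* `causal_autonomy` and the transient measures require deterministic
  agents; the panel records them as missing (with the reason) for
  stochastic ones.
* The actual-causation account evaluates direct causes over one time
  step only; tracing causes of causes across multiple steps is out of
  scope.
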