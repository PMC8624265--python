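"""Mechanism- and system-level integrated information (IIT 3.0).

Implements the compositional causal analysis of discrete binary
networks: interventional cause/effect repertoires of mechanisms over
purviews, small phi as the earth-mover's distance to the
minimum-information partition (MIP), cause-effect structures, and big
Phi as the minimal concept-space distance over unidirectional system
cuts.  Conventions follow the published IIT 3.0 account: repertoire
distances use the EMD with Hamming ground metric; mechanism partitions
are bipartitions of (mechanism, purview); system cuts sever the
connections from one part to the rest, which are replaced by
independent noise; units outside the candidate system are background
conditions frozen in their current state; values are reported to six
decimals.

State indexing is little-endian throughout (unit 0 is the
least-significant bit).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .agent import Agent
from .emd import emd, emd_lower_bound, hamming_emd

__all__ = [
    "CandidateSystem",
    "Mice",
    "Concept",
    "CauseEffectStructure",
    "MajorComplexResult",
    "phi_mechanism",
    "sum_phi_whole",
    "major_complex",
]

EPSILON = 1e-6
PRECISION = 6

CAUSE = "cause"
EFFECT = "effect"

_ONE = np.array([1.0])


def _nonempty_subsets(units, reverse=False):
    units = sorted(units)
    sizes = range(len(units), 0, -1) if reverse else range(1, len(units) + 1)
    for k in sizes:
        yield from itertools.combinations(units, k)


def _bipartitions_unordered(items):
    """All splits of ``items`` into two unordered parts (first part may be empty)."""
    items = tuple(items)
    n = len(items)
    out = []
    for mask in range(1 << max(n - 1, 0)):
        part0 = tuple(items[i] for i in range(n) if (mask >> i) & 1)
        part1 = tuple(items[i] for i in range(n) if not (mask >> i) & 1)
        out.append((part0, part1))
    return out


def _directed_bipartitions(items):
    items = tuple(items)
    n = len(items)
    out = []
    for mask in range(1 << n):
        part0 = tuple(items[i] for i in range(n) if (mask >> i) & 1)
        part1 = tuple(items[i] for i in range(n) if not (mask >> i) & 1)
        out.append((part0, part1))
    return out


@dataclass
class Mice:
    """Maximally irreducible cause or effect of a mechanism."""

    direction: str
    phi: float
    purview: tuple
    repertoire: np.ndarray  # flat, little-endian over the purview


@dataclass
class Concept:
    """A mechanism with its maximally irreducible cause and effect."""

    mechanism: tuple  # positions within the candidate system
    phi: float
    cause: Mice
    effect: Mice
    system: "CandidateSystem" = field(repr=False, default=None)


class CauseEffectStructure(list):
    """The set of concepts (phi > 0 mechanisms) of a candidate system."""

    @property
    def sum_phi(self) -> float:
        return float(sum(c.phi for c in self))

    @property
    def mechanisms(self):
        return [c.mechanism for c in self]


@dataclass
class MajorComplexResult:
    """Winning candidate subset and its integrated information."""

    nodes: tuple      # global unit indices of the major complex
    phi: float        # big Phi
    sum_phi: float    # sum of small phi over the major complex's concepts
    n_concepts: int
    candidate_phis: dict  # subset -> Phi for every evaluated candidate


class CandidateSystem:
    """A candidate subsystem of a binary network, with optional cut.

    Parameters
    ----------
    tpm
        Full-network state-by-node TPM, ``(2**n, n)``.
    cm
        Full-network connectivity matrix.
    state
        Full-network current state (length n).
    nodes
        Global indices of the candidate system's units; all other units
        are frozen at their state as background conditions.
    cut
        Optional ``(from_part, to_part)`` pair of tuples of *positions*
        within ``nodes``; connections from ``from_part`` to ``to_part``
        are severed and replaced by independent maximum-entropy noise.
    shared_cache
        Optional dict reused across systems that differ only in the
        states of units outside every mechanism (repertoires depend on
        the mechanism state only).
    """

    def __init__(self, tpm, cm, state, nodes, cut=None, shared_cache=None):
        self.tpm = np.asarray(tpm, dtype=float)
        self.cm = np.asarray(cm, dtype=int)
        self.state = tuple(int(b) for b in state)
        self.nodes = tuple(sorted(nodes))
        self.cut = cut
        n_all = self.tpm.shape[1]
        self.n = len(self.nodes)
        self.sub_state = tuple(self.state[u] for u in self.nodes)
        node_set = set(self.nodes)

        severed = set()
        if cut is not None:
            frm, to = cut
            for a in frm:
                for b in to:
                    severed.add((a, b))

        # per-node activation probability over candidate configurations
        self._p1 = []
        # connectivity among candidate positions, cut applied
        self.cm_sub = np.zeros((self.n, self.n), dtype=bool)
        for b_pos, j in enumerate(self.nodes):
            col = self.tpm[:, j].reshape((2,) * n_all, order="F")
            for i in range(n_all):
                if i not in node_set:  # background conditioning, axis kept
                    col = np.take(col, [self.state[i]], axis=i)
            for a_pos, i in enumerate(self.nodes):
                if (a_pos, b_pos) in severed:
                    col = col.mean(axis=i, keepdims=True)
                self.cm_sub[a_pos, b_pos] = bool(self.cm[i, j]) and (
                    (a_pos, b_pos) not in severed
                )
            col = np.broadcast_to(col, (2,) * n_all)
            col = col[tuple(0 if i not in node_set else slice(None)
                            for i in range(n_all))]
            self._p1.append(np.ascontiguousarray(col))

        self._cache = shared_cache if shared_cache is not None else {}
        self._cut_key = (tuple(sorted(cut[0])), tuple(sorted(cut[1]))) if cut else None

    def state_reachable(self) -> bool:
        """Whether the candidate system's joint state has a possible cause.

        Candidates whose current state cannot follow from any previous
        configuration (given the background conditions) do not specify
        cause repertoires and cannot form complexes.
        """
        joint = np.ones((2,) * self.n)
        for a in range(self.n):
            f = self._p1[a] if self.sub_state[a] else 1.0 - self._p1[a]
            joint = joint * f
        return bool(joint.any())

    # -- repertoires -------------------------------------------------------
    def _key(self, kind, mech, purview):
        mstate = tuple(self.sub_state[a] for a in mech)
        return (kind, self._cut_key, mech, mstate, purview)

    def cause_repertoire(self, mech, purview) -> np.ndarray:
        """Interventional distribution over past purview states.

        Bayesian inversion of the mechanism's units given their current
        state, with a uniform prior over the purview and non-purview
        inputs marginalized uniformly.  All-zero if the mechanism state
        is unreachable from the purview (no cause).
        """
        if not purview:
            return _ONE
        if not mech:
            return np.full(1 << len(purview), 2.0 ** -len(purview))
        key = self._key(CAUSE, mech, purview)
        hit = self._cache.get(key)
        if hit is None:
            other_axes = tuple(a for a in range(self.n) if a not in purview)
            joint = np.ones((2,) * len(purview))
            for m in mech:
                f = self._p1[m] if self.sub_state[m] else 1.0 - self._p1[m]
                joint = joint * (f.mean(axis=other_axes) if other_axes else f)
            flat = joint.ravel(order="F")
            total = flat.sum()
            hit = flat / total if total > 0 else flat
            self._cache[key] = hit
        return hit

    def effect_repertoire(self, mech, purview) -> np.ndarray:
        """Interventional distribution over future purview states.

        Mechanism units are clamped to their current state, all other
        inputs set to independent maximum-entropy noise; purview units
        are conditionally independent, so the repertoire is a product of
        Bernoulli factors.
        """
        if not purview:
            return _ONE
        key = self._key(EFFECT, tuple(mech), purview)
        hit = self._cache.get(key)
        if hit is None:
            mech_set = set(mech)
            idx = tuple(self.sub_state[a] if a in mech_set else slice(None)
                        for a in range(self.n))
            rep = _ONE
            for p in purview:
                p1 = float(np.mean(self._p1[p][idx]))
                rep = np.kron(np.array([1.0 - p1, p1]), rep)
            hit = rep
            self._cache[key] = hit
        return hit

    def repertoire(self, direction, mech, purview) -> np.ndarray:
        if direction == CAUSE:
            return self.cause_repertoire(mech, purview)
        return self.effect_repertoire(mech, purview)

    def unconstrained_repertoire(self, direction, purview) -> np.ndarray:
        return self.repertoire(direction, (), purview)

    @staticmethod
    def _combine(purview, parts) -> np.ndarray:
        """Assemble part repertoires into one distribution over ``purview``."""
        full = np.ones(1 << len(purview))
        states = np.arange(1 << len(purview))
        pos_of = {u: k for k, u in enumerate(purview)}
        for sub, rep in parts:
            if not sub:
                continue
            sub_idx = np.zeros_like(states)
            for kk, u in enumerate(sub):
                sub_idx |= ((states >> pos_of[u]) & 1) << kk
            full = full * rep[sub_idx]
        return full

    @staticmethod
    def _effect_distance(r1, r2, n_bits) -> float:
        """EMD between factorizable effect repertoires: summed marginal shifts."""
        states = np.arange(1 << n_bits)
        d = 0.0
        for b in range(n_bits):
            off = ((states >> b) & 1) == 0
            d += abs(float(r1[off].sum()) - float(r2[off].sum()))
        return d

    # -- mechanism-level analysis -----------------------------------------
    def find_mip(self, direction, mech, purview, abort_under=None):
        """phi of the minimum-information partition for mechanism/purview.

        Returns ``(phi, exact)``; when ``abort_under`` is given the
        search stops as soon as the running minimum falls strictly below
        it (the returned value is then an upper bound, flagged inexact).
        """
        mech = tuple(sorted(mech))
        purview = tuple(sorted(purview))
        if not purview:
            return 0.0, True
        key = self._key(("mip", direction), mech, purview)
        hit = self._cache.get(key)
        if hit is not None:
            return hit, True
        whole = self.repertoire(direction, mech, purview)
        if direction == CAUSE and not whole.any():
            self._cache[key] = 0.0
            return 0.0, True

        partitions = []
        for n0, n1 in _bipartitions_unordered(mech):
            for d0, d1 in _directed_bipartitions(purview):
                if (n0 or d0) and (n1 or d1):
                    partitions.append((n0, n1, d0, d1))
        # cheap partitions first: single-element separations tend to expose
        # reducibility immediately
        partitions.sort(key=lambda p: min(len(p[0]) + len(p[2]), len(p[1]) + len(p[3])))

        best = np.inf
        nb = len(purview)
        for n0, n1, d0, d1 in partitions:
            part = self._combine(
                purview,
                [(d0, self.repertoire(direction, n0, d0)),
                 (d1, self.repertoire(direction, n1, d1))],
            )
            if direction == CAUSE:
                if emd_lower_bound(whole, part, nb) >= best:
                    continue
                d = round(hamming_emd(whole, part, nb), PRECISION)
            else:
                d = round(self._effect_distance(whole, part, nb), PRECISION)
            if d == 0.0:
                self._cache[key] = 0.0
                return 0.0, True
            if d < best:
                best = d
                if abort_under is not None and best < abort_under:
                    return best, False
        best = float(best)
        self._cache[key] = best
        return best, True

    def _potential_purviews(self, direction, mech):
        if direction == CAUSE:
            pool = [a for a in range(self.n) if self.cm_sub[a, list(mech)].any()]
        else:
            pool = [a for a in range(self.n) if self.cm_sub[list(mech), a].any()]
        return list(_nonempty_subsets(pool))

    def find_mice(self, direction, mech) -> Mice:
        """Maximally irreducible cause/effect: the purview maximizing phi.

        Ties prefer larger purviews, then the earliest in the
        size-ascending lexicographic enumeration.
        """
        mech = tuple(sorted(mech))
        best_phi, best_purview = 0.0, None
        for purview in self._potential_purviews(direction, mech):
            phi, exact = self.find_mip(direction, mech, purview,
                                       abort_under=best_phi)
            if not exact:
                continue
            if best_purview is None and phi >= best_phi:
                best_phi, best_purview = phi, purview
            elif (phi, len(purview)) > (best_phi, len(best_purview)):
                best_phi, best_purview = phi, purview
        if best_purview is None:
            return Mice(direction, 0.0, (), _ONE.copy())
        return Mice(direction, best_phi, best_purview,
                    self.repertoire(direction, mech, best_purview))

    def concept(self, mech) -> Concept:
        mech = tuple(sorted(mech))
        cause = self.find_mice(CAUSE, mech)
        effect = self.find_mice(EFFECT, mech)
        phi = round(min(cause.phi, effect.phi), PRECISION)
        return Concept(mech, phi, cause, effect, system=self)

    def _mechanism_candidates(self):
        """Mechanisms that can have phi > 0: every unit needs an input from
        and an output to the candidate system (anything else is exactly
        reducible by splitting that unit off)."""
        viable = [
            a for a in range(self.n)
            if self.cm_sub[:, a].any() and self.cm_sub[a, :].any()
        ]
        return list(_nonempty_subsets(viable))

    def ces(self, mechanisms=None) -> CauseEffectStructure:
        """All concepts (mechanisms with phi > 0) of the candidate system."""
        out = CauseEffectStructure()
        if mechanisms is None:
            mechanisms = self._mechanism_candidates()
        for mech in mechanisms:
            c = self.concept(tuple(sorted(mech)))
            if c.phi > EPSILON:
                out.append(c)
        return out

    def null_concept(self) -> Concept:
        cause = Mice(CAUSE, 0.0, (), _ONE.copy())
        effect = Mice(EFFECT, 0.0, (), _ONE.copy())
        return Concept((), 0.0, cause, effect, system=self)


# -- concept space ---------------------------------------------------------

def _expand(system: CandidateSystem, direction, mice: Mice, new_purview) -> np.ndarray:
    """Distribute a repertoire over a larger purview.

    Missing units receive their unconstrained repertoire (uniform on the
    cause side, the empty-mechanism effect repertoire on the effect
    side); the product is renormalized.
    """
    new_purview = tuple(sorted(new_purview))
    missing = tuple(sorted(set(new_purview) - set(mice.purview)))
    parts = [(mice.purview, mice.repertoire)]
    if missing:
        parts.append((missing, system.unconstrained_repertoire(direction, missing)))
    full = CandidateSystem._combine(new_purview, parts)
    total = full.sum()
    return full / total if total > 0 else full


def concept_distance(c1: Concept, c2: Concept) -> float:
    """Distance between two concepts: summed cause- and effect-side EMDs
    over the union of their purviews."""
    d = 0.0
    for direction in (CAUSE, EFFECT):
        m1 = c1.cause if direction == CAUSE else c1.effect
        m2 = c2.cause if direction == CAUSE else c2.effect
        union = tuple(sorted(set(m1.purview) | set(m2.purview)))
        if not union:
            continue
        r1 = _expand(c1.system, direction, m1, union)
        r2 = _expand(c2.system, direction, m2, union)
        d += hamming_emd(r1, r2, len(union))
    return d


def _emd_eq(c1: Concept, c2: Concept) -> bool:
    return (
        c1.mechanism == c2.mechanism
        and c1.phi == c2.phi
        and c1.cause.purview == c2.cause.purview
        and c1.effect.purview == c2.effect.purview
        and np.allclose(c1.cause.repertoire, c2.cause.repertoire, atol=1e-12)
        and np.allclose(c1.effect.repertoire, c2.effect.repertoire, atol=1e-12)
    )


def ces_distance(C1: CauseEffectStructure, C2: CauseEffectStructure) -> float:
    """Extended EMD between cause-effect structures in concept space.

    Concepts that simply disappear move to the null concept; otherwise a
    transportation problem over the unmatched concepts (with the null
    concept absorbing the phi difference) is solved, with pairwise
    concept distances as ground metric.
    """
    only1 = [c for c in C1 if not any(_emd_eq(c, d) for d in C2)]
    only2 = [c for c in C2 if not any(_emd_eq(c, d) for d in C1)]
    if not only1 or not only2:
        bigger, smaller = (C2, C1) if len(C2) > len(C1) else (C1, C2)
        destroyed = [c for c in bigger if not any(_emd_eq(c, d) for d in smaller)]
        dist = sum(
            c.phi * concept_distance(c, c.system.null_concept()) for c in destroyed
        )
        return round(float(dist), PRECISION)

    n1, n2 = len(only1), len(only2)
    pairwise = np.array([[concept_distance(a, b) for b in only2] for a in only1])
    to_null = np.array(
        [concept_distance(c, c.system.null_concept()) for c in only1 + only2]
    )
    size = n1 + n2 + 1
    dm = np.full((size, size), pairwise.max() + 1.0)
    dm[:n1, n1:-1] = pairwise
    dm[n1:-1, :n1] = pairwise.T
    dm[-1, :-1] = to_null
    dm[:-1, -1] = to_null
    dm[-1, -1] = 0.0
    d1 = np.array([c.phi for c in only1] + [0.0] * n2 + [0.0])
    d2 = np.array([0.0] * n1 + [c.phi for c in only2] + [0.0])
    # the phi surplus moves to the null concept on whichever side is lighter
    diff = d1.sum() - d2.sum()
    if diff >= 0:
        d2[-1] = diff
    else:
        d1[-1] = -diff
    return round(emd(d1, d2, dm), PRECISION)


# -- system level ----------------------------------------------------------

def _strongly_connected(cm_sub: np.ndarray) -> bool:
    n = cm_sub.shape[0]
    reach = cm_sub.astype(int) | np.eye(n, dtype=int)
    for _ in range(n):
        reach = ((reach @ reach) > 0).astype(int)
    return bool(reach.all())


def big_phi(tpm, cm, state, nodes, shared_cache=None):
    """Big Phi of one candidate system: minimal concept-space distance
    between the intact cause-effect structure and that of the system
    under any unidirectional cut.

    Returns ``(Phi, ces)``.  Zero for single units, for candidates that
    are not strongly connected, and for empty cause-effect structures.
    """
    nodes = tuple(sorted(nodes))
    system = CandidateSystem(tpm, cm, state, nodes, shared_cache=shared_cache)
    if system.n < 2 or not _strongly_connected(system.cm_sub):
        return 0.0, CauseEffectStructure()
    if not system.state_reachable():
        return 0.0, CauseEffectStructure()
    ces = system.ces()
    if not ces:
        return 0.0, ces
    positions = tuple(range(system.n))
    best = np.inf
    for frm, to in _directed_bipartitions(positions):
        if not frm or not to:
            continue
        cut_system = CandidateSystem(tpm, cm, state, nodes, cut=(frm, to))
        split = [
            m for m in cut_system._mechanism_candidates()
            if set(m) & set(frm) and set(m) & set(to)
        ]
        mechanisms = sorted(set(ces.mechanisms) | set(split))
        cut_ces = cut_system.ces(mechanisms)
        dist = ces_distance(ces, cut_ces)
        if dist < best:
            best = dist
            if best == 0.0:
                break
    return float(best), ces


# -- public agent-level API ------------------------------------------------

def phi_mechanism(agent: Agent, system_state, candidate_system, mechanism):
    """Small phi of one mechanism within a candidate system of hidden units.

    ``candidate_system`` and ``mechanism`` are global unit indices;
    units outside the candidate system are background conditions frozen
    at ``system_state``.  Returns ``(phi, cause_purview, effect_purview)``
    with purviews as global indices (empty tuples when the mechanism has
    no cause or effect).
    """
    candidate = tuple(sorted(candidate_system))
    if not set(mechanism) <= set(candidate):
        raise ValueError("mechanism must lie within the candidate system")
    system = CandidateSystem(agent.tpm, agent.cm, system_state, candidate)
    pos = {u: i for i, u in enumerate(candidate)}
    mech = tuple(sorted(pos[u] for u in mechanism))
    concept = system.concept(mech)
    to_global = lambda pv: tuple(candidate[a] for a in pv)  # noqa: E731
    return (
        concept.phi,
        to_global(concept.cause.purview) if concept.phi > EPSILON else (),
        to_global(concept.effect.purview) if concept.phi > EPSILON else (),
    )


def sum_phi_whole(agent: Agent, system_state, shared_cache=None):
    """Compositional causal complexity of the full system in one state.

    Sums small phi over all mechanisms of the whole network (sensors and
    motors included as candidate units; mechanisms containing units
    without inputs or outputs are exactly reducible and contribute 0).
    Returns ``(sum_phi, n_mechanisms)``.
    """
    system = CandidateSystem(
        agent.tpm, agent.cm, system_state, tuple(range(agent.n_units)),
        shared_cache=shared_cache,
    )
    ces = system.ces()
    return ces.sum_phi, len(ces)


def major_complex(agent: Agent, system_state, shared_cache=None) -> MajorComplexResult:
    """The hidden-unit subset with maximal big Phi.

    Candidate systems range over all non-empty subsets of hidden units
    (sensors feed in and motors read out in a feed-forward manner, so
    only hidden units can be strongly connected).  Ties prefer larger
    Phi, then larger subsets, then the earliest enumerated.
    """
    best = MajorComplexResult((), 0.0, 0.0, 0, {})
    phis = {}
    for subset in _nonempty_subsets(agent.hidden_idx):
        phi, ces = big_phi(agent.tpm, agent.cm, system_state, subset,
                           shared_cache=shared_cache)
        phis[subset] = phi
        if (phi, len(subset)) > (best.phi, len(best.nodes)):
            best = MajorComplexResult(subset, phi, ces.sum_phi, len(ces), {})
    return MajorComplexResult(best.nodes, best.phi, best.sum_phi,
                              best.n_concepts, phis)
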