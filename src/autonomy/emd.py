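"""Exact earth mover's distance with a Hamming ground metric.

Repertoire comparisons in the causal module use the EMD between
probability distributions over binary purview states, with the Hamming
distance between states as the transportation cost.  Distances are
solved exactly as transportation linear programs (HiGHS), restricted to
the joint support.  Cheap lower bounds (total variation; summed
per-bit marginal discrepancies) are exposed for search pruning.
"""

from __future__ import annotations

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

__all__ = ["hamming_emd", "emd", "emd_lower_bound"]

_cache: dict = {}
_CACHE_MAX = 200_000


def _popcount(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x)
    if hasattr(np, "bitwise_count"):
        return np.bitwise_count(x)
    return np.array([bin(v).count("1") for v in x.ravel()]).reshape(x.shape)


def emd(p: np.ndarray, q: np.ndarray, cost: np.ndarray) -> float:
    """Exact EMD between two distributions under an arbitrary cost matrix."""
    p = np.asarray(p, dtype=float).ravel()
    q = np.asarray(q, dtype=float).ravel()
    si = np.nonzero(p > 0)[0]
    sj = np.nonzero(q > 0)[0]
    ps, qs = p[si], q[sj]
    c = cost[np.ix_(si, sj)]
    n, m = len(ps), len(qs)
    if n == 1:
        return float((qs * c[0]).sum())
    if m == 1:
        return float((ps * c[:, 0]).sum())
    # transportation LP: rows supply ps, columns demand qs
    row_ind, col_ind, data = [], [], []
    for i in range(n):
        row_ind.extend([i] * m)
        col_ind.extend(range(i * m, (i + 1) * m))
        data.extend([1.0] * m)
    for j in range(m):
        row_ind.extend([n + j] * n)
        col_ind.extend(range(j, n * m, m))
        data.extend([1.0] * n)
    A = sparse.csr_matrix((data, (row_ind, col_ind)), shape=(n + m, n * m))
    b = np.concatenate([ps, qs])
    res = linprog(c.ravel(), A_eq=A, b_eq=b, bounds=(0, None), method="highs")
    if not res.success:  # pragma: no cover - HiGHS is reliable on feasible LPs
        raise RuntimeError(f"EMD transportation LP failed: {res.message}")
    return float(res.fun)


def emd_lower_bound(p: np.ndarray, q: np.ndarray, n_bits: int) -> float:
    """Cheap lower bound on the Hamming EMD.

    Combines total variation (every moved unit of mass travels at least
    distance 1) and the summed per-bit marginal discrepancies (a unit of
    mass moved over Hamming distance d shifts d single-bit marginals).
    """
    tv = 0.5 * float(np.abs(p - q).sum())
    states = np.arange(p.size)
    marg = 0.0
    for b in range(n_bits):
        on = ((states >> b) & 1).astype(bool)
        marg += abs(float(p[on].sum() - q[on].sum()))
    return max(tv, marg)


def hamming_emd(p: np.ndarray, q: np.ndarray, n_bits: int) -> float:
    """Exact EMD over little-endian indexed binary states, memoized."""
    p = np.asarray(p, dtype=float).ravel()
    q = np.asarray(q, dtype=float).ravel()
    if p.size != (1 << n_bits) or q.size != p.size:
        raise ValueError("distribution size must be 2**n_bits")
    if np.array_equal(p, q):
        return 0.0
    key = (p.tobytes(), q.tobytes())
    hit = _cache.get(key)
    if hit is not None:
        return hit
    states = np.arange(1 << n_bits)
    cost = _popcount(np.bitwise_xor.outer(states, states)).astype(float)
    val = emd(p, q, cost)
    if len(_cache) > _CACHE_MAX:
        _cache.clear()
    _cache[key] = val
    return val
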