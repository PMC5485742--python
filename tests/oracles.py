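"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive: plain Python loops, exact integer
combinatorics, exhaustive enumeration.  These implementations must stay
independent of the package code paths they check.
"""

from __future__ import annotations

import math
from functools import lru_cache


# ---------------------------------------------------------------------------
# dense loop-based MCL
# ---------------------------------------------------------------------------

def naive_mcl(
    nodes: list[str],
    edges: dict[tuple[str, str], float],
    inflation: float,
    max_iterations: int = 200,
    tol: float = 1e-6,
    prune: float = 1e-7,
    self_loop_rule: str = "max_incident",
) -> set[frozenset[str]]:
    """Loop-based MCL: expansion (square), inflation, prune, renormalize.

    Returns the partition as a set of frozensets of node ids.
    """
    nodes = sorted(nodes)
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    m = [[0.0] * n for _ in range(n)]
    for (u, v), w in edges.items():
        if u == v:
            continue
        m[idx[u]][idx[v]] = w
        m[idx[v]][idx[u]] = w
    for j in range(n):
        if self_loop_rule == "max_incident":
            best = max(m[i][j] for i in range(n))
            m[j][j] = best if best > 0 else 1.0
        else:
            m[j][j] = 1.0

    def normalize(mat: list[list[float]]) -> None:
        for j in range(n):
            s = sum(mat[i][j] for i in range(n))
            if s == 0:
                mat[j][j] = 1.0
                s = 1.0
            for i in range(n):
                mat[i][j] /= s

    normalize(m)
    for _ in range(max_iterations):
        prev = [row[:] for row in m]
        # expansion: matrix square by triple loop
        sq = [[0.0] * n for _ in range(n)]
        for i in range(n):
            for k in range(n):
                mik = m[i][k]
                if mik == 0.0:
                    continue
                for j in range(n):
                    sq[i][j] += mik * m[k][j]
        # inflation
        for i in range(n):
            for j in range(n):
                sq[i][j] = sq[i][j] ** inflation
        normalize(sq)
        for i in range(n):
            for j in range(n):
                if sq[i][j] < prune:
                    sq[i][j] = 0.0
        normalize(sq)
        m = sq
        delta = max(
            max(abs(m[i][j] - prev[i][j]) for i in range(n)) for j in range(n)
        )
        if delta < tol:
            break

    # interpretation: attractors are rows with positive diagonal; each node
    # joins every attractor it flows to; overlapping sets merge
    clusters: list[set[int]] = []
    for a in range(n):
        if m[a][a] > 0:
            members = {a} | {j for j in range(n) if m[a][j] > 0}
            clusters.append(members)
    merged = True
    while merged:
        merged = False
        for x in range(len(clusters)):
            for y in range(x + 1, len(clusters)):
                if clusters[x] & clusters[y]:
                    clusters[x] |= clusters[y]
                    del clusters[y]
                    merged = True
                    break
            if merged:
                break
    assigned = set().union(*clusters) if clusters else set()
    for j in range(n):
        if j not in assigned:
            target = max(range(n), key=lambda i: m[i][j])
            for cl in clusters:
                if target in cl:
                    cl.add(j)
                    break
            else:
                clusters.append({j, target})
            assigned.add(j)
    return {frozenset(nodes[i] for i in cl) for cl in clusters}


# ---------------------------------------------------------------------------
# exact combinatorics
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def _comb(n: int, k: int) -> int:
    return math.comb(n, k)


def hypergeom_pmf(k: int, N: int, K: int, n: int) -> float:
    """P[X = k] for X ~ Hypergeometric(N, K, n), exact integer arithmetic."""
    if k < max(0, n + K - N) or k > min(n, K):
        return 0.0
    return _comb(K, k) * _comb(N - K, n - k) / _comb(N, n)


def hypergeom_sf_inclusive(k: int, N: int, K: int, n: int) -> float:
    """Upper tail P[X >= k] by summation over the support."""
    return sum(hypergeom_pmf(j, N, K, n) for j in range(max(k, 0), min(n, K) + 1))


def fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p by the point-mass rule, full enumeration.

    Sums the probability of every table with the same margins whose
    probability does not exceed the observed one (with the customary
    relative slack for floating-point ties).
    """
    N = a + b + c + d
    r, col = a + b, a + c
    p_obs = hypergeom_pmf(a, N, col, r)
    total = 0.0
    for x in range(max(0, r + col - N), min(r, col) + 1):
        p = hypergeom_pmf(x, N, col, r)
        if p <= p_obs * (1 + 1e-7):
            total += p
    return min(total, 1.0)


def chi_square_yates_statistic(a: int, b: int, c: int, d: int) -> float:
    """Direct evaluation of the Yates-corrected chi-square expression."""
    n = a + b + c + d
    num = abs(a * d - b * c) - n / 2
    if num < 0:
        num = 0.0
    return n * num * num / ((a + b) * (c + d) * (a + c) * (b + d))


# ---------------------------------------------------------------------------
# naive sliding-window scan
# ---------------------------------------------------------------------------

def naive_window_max(sequence: str, residue_set: frozenset[str], window: int = 20, step: int = 1) -> int:
    """Count residues window by window; no rolling tricks."""
    if len(sequence) <= window:
        return sum(ch in residue_set for ch in sequence)
    best = 0
    for start in range(0, len(sequence) - window + 1, step):
        count = sum(ch in residue_set for ch in sequence[start : start + window])
        if count > best:
            best = count
    return best
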