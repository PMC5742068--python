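"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own algorithms: direct substring
scans, full O(nm) dynamic programming in plain Python, exhaustive subset
enumeration, and permutation enumeration.
"""
from __future__ import annotations

import itertools
from functools import lru_cache

import numpy as np

VALID = set("ACGT")


def brute_force_mems(ref: str, qry: str, min_len: int, unique_in_ref: bool = True):
    """All maximal exact matches by direct scanning.

    Returns a set of (ref_start, qry_start, length). N never matches.
    """
    n, m = len(ref), len(qry)
    eq = np.zeros((n, m), dtype=bool)
    for i, c in enumerate(ref):
        if c in VALID:
            eq[i] = np.frombuffer(qry.encode(), dtype="S1") == c.encode()
    out = set()
    for i in range(n):
        for j in range(m):
            if not eq[i, j]:
                continue
            if i > 0 and j > 0 and eq[i - 1, j - 1]:
                continue  # not a run start
            l = 0
            while i + l < n and j + l < m and eq[i + l, j + l]:
                l += 1
            if l < min_len:
                continue
            if unique_in_ref:
                sub = ref[i : i + l]
                count = sum(1 for k in range(n - l + 1) if ref[k : k + l] == sub)
                if count != 1:
                    continue
            out.add((i, j, l))
    return out


def full_dp_affine_score(
    a: str, b: str, match=1.0, mismatch=-1.0, gap_open=-2.0, gap_ext=-0.5
) -> float:
    """Unconstrained affine-gap global alignment score, plain Python."""
    n, m = len(a), len(b)
    NEG = float("-inf")
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    for j in range(1, m + 1):
        H[0][j] = E[0][j] = gap_open + gap_ext * j
    for i in range(1, n + 1):
        H[i][0] = F[i][0] = gap_open + gap_ext * i
        ai = a[i - 1]
        Hi, Hi1, Ei, Fi, Fi1 = H[i], H[i - 1], E[i], F[i], F[i - 1]
        for j in range(1, m + 1):
            e = max(Ei[j - 1] + gap_ext, Hi[j - 1] + gap_open + gap_ext)
            f = max(Fi1[j] + gap_ext, Hi1[j] + gap_open + gap_ext)
            s = match if (ai == b[j - 1] and ai in VALID) else mismatch
            Ei[j], Fi[j] = e, f
            Hi[j] = max(Hi1[j - 1] + s, e, f)
    return H[n][m]


def brute_force_max_weight_consistent(blocks, mode: str = "one-to-one", tol: int = 50):
    """Optimal weight of a conflict-free subset by subset enumeration.

    ``blocks`` are (ref_start, ref_end, qry_start, qry_end, weight)
    tuples on a single sequence pair.
    """
    def conflict(x, y):
        if mode in ("one-to-one", "ref"):
            if min(x[1], y[1]) - max(x[0], y[0]) > tol:
                return True
        if mode in ("one-to-one", "query"):
            if min(x[3], y[3]) - max(x[2], y[2]) > tol:
                return True
        return False

    best = 0.0
    n = len(blocks)
    for r in range(1, n + 1):
        for combo in itertools.combinations(range(n), r):
            if any(
                conflict(blocks[i], blocks[j])
                for i, j in itertools.combinations(combo, 2)
            ):
                continue
            best = max(best, sum(blocks[i][4] for i in combo))
    return best


@lru_cache(maxsize=None)
def _u_null_distribution(n1: int, n2: int):
    """Exact null distribution of the Mann-Whitney U statistic (tie-free)."""
    N = n1 + n2
    counts: dict[float, int] = {}
    for combo in itertools.combinations(range(N), n1):
        rank_sum = sum(combo) + n1  # ranks are 1-based
        u = rank_sum - n1 * (n1 + 1) / 2
        counts[u] = counts.get(u, 0) + 1
    return counts


def permutation_ranksum_p(x, y) -> float:
    """Two-sided rank-sum p by full permutation enumeration (no ties)."""
    pooled = sorted(list(x) + list(y))
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    n1, n2 = len(x), len(y)
    u_obs = sum(ranks[v] for v in x) - n1 * (n1 + 1) / 2
    dist = _u_null_distribution(n1, n2)
    total = sum(dist.values())
    mu = n1 * n2 / 2
    extreme = sum(c for u, c in dist.items() if abs(u - mu) >= abs(u_obs - mu))
    return extreme / total


def chi2_tail_by_integration(x: float, df: int) -> float:
    """Upper chi-square tail via numerical integration of the density."""
    import math

    from scipy.integrate import quad

    def pdf(t):
        return (
            t ** (df / 2 - 1)
            * math.exp(-t / 2)
            / (2 ** (df / 2) * math.gamma(df / 2))
        )

    val, _ = quad(pdf, x, max(x * 10, x + 200), limit=200)
    return val
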