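"""Independent brute-force oracles used to validate the fast implementations.

Each oracle re-derives its answer from first principles (exhaustive
enumeration) and never calls the code path it checks.
"""

from __future__ import annotations

from math import comb

_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


def brute_force_palindromes(
    seq: str,
    min_arm: int = 4,
    max_arm: int = 20,
    max_gap: int = 5,
    max_mismatch: int = 1,
) -> list[tuple[int, int, int, int]]:
    """Every maximal inverted repeat (start, arm, gap, mismatches) by
    exhaustive enumeration of all (start, arm, gap) triples.

    A triple is maximal when growing both arm ends outward by one base --
    staying inside the sequence and the arm-length bound -- would exceed the
    mismatch budget.
    """
    seq = seq.upper()
    n = len(seq)

    def mismatches(i: int, arm: int, gap: int) -> int:
        count = 0
        for j in range(arm):
            if (seq[i + j], seq[i + 2 * arm + gap - 1 - j]) not in _PAIRS:
                count += 1
        return count

    hits = []
    for gap in range(max_gap + 1):
        for arm in range(min_arm, max_arm + 1):
            for i in range(0, n - 2 * arm - gap + 1):
                m = mismatches(i, arm, gap)
                if m > max_mismatch:
                    continue
                extendable = (
                    i - 1 >= 0
                    and i + 2 * arm + gap < n
                    and arm + 1 <= max_arm
                    and mismatches(i - 1, arm + 1, gap) <= max_mismatch
                )
                if extendable:
                    continue
                hits.append((i, arm, gap, m))
    return sorted(hits)


def hypergeom_pmf(a: int, row1: int, row2: int, col1: int) -> float:
    """P(top-left cell = a) for a 2x2 table with fixed margins."""
    n = row1 + row2
    return comb(row1, a) * comb(row2, col1 - a) / comb(n, col1)


def fisher_two_sided(table) -> float:
    """Two-sided Fisher exact p by full enumeration over the hypergeometric
    support: sum of probabilities of all tables at most as probable as the
    observed one (with a small relative tolerance for float ties)."""
    (a, b), (c, d) = table
    row1, row2 = a + b, c + d
    col1 = a + c
    lo = max(0, col1 - row2)
    hi = min(col1, row1)
    p_obs = hypergeom_pmf(a, row1, row2, col1)
    total = 0.0
    for k in range(lo, hi + 1):
        p = hypergeom_pmf(k, row1, row2, col1)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return min(total, 1.0)


def nnls_grid_residual(v, S, grid_max: float, steps: int) -> float:
    """Best residual over a coarse grid of non-negative activity vectors.

    Exhaustive search over steps^k grid points; only feasible for k <= 4.
    """
    import itertools

    import numpy as np

    v = np.asarray(v, dtype=float)
    S = np.asarray(S, dtype=float)
    k = S.shape[1]
    axis = np.linspace(0.0, grid_max, steps)
    best = float("inf")
    for combo in itertools.product(axis, repeat=k):
        r = np.linalg.norm(v - S @ np.asarray(combo))
        best = min(best, r)
    return best
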