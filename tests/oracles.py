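"""Independent oracles used by the test suite.

These are deliberately separate implementations from the package code:
a plain-Python Gotoh dynamic program for local alignment with affine gaps,
and, for very short sequences, a jump-recursion enumerator that considers
every local alignment path explicitly. Both use the same cost convention
as the production aligner (gap of length k costs open + k = 11 + k with
BLOSUM62 substitution scores).
"""

from __future__ import annotations

from functools import lru_cache

from Bio.Align import substitution_matrices

_BLOSUM62 = substitution_matrices.load("BLOSUM62")

GAP_OPEN = 11  # a gap of length k costs GAP_OPEN + k * GAP_EXTEND
GAP_EXTEND = 1


def blosum(a: str, b: str) -> float:
    return float(_BLOSUM62[a][b])


def gotoh_local_score(q: str, t: str) -> float:
    """Smith-Waterman-Gotoh local alignment score, pure Python."""
    n, m = len(q), len(t)
    neg = float("-inf")
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[neg] * (m + 1) for _ in range(n + 1)]  # gap in query (along t)
    F = [[neg] * (m + 1) for _ in range(n + 1)]  # gap in target
    best = 0.0
    first = GAP_OPEN + GAP_EXTEND  # cost of a length-1 gap
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - first, E[i][j - 1] - GAP_EXTEND)
            F[i][j] = max(H[i - 1][j] - first, F[i - 1][j] - GAP_EXTEND)
            H[i][j] = max(0.0,
                          H[i - 1][j - 1] + blosum(q[i - 1], t[j - 1]),
                          E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def exhaustive_local_score(q: str, t: str) -> float:
    """Enumerate every local alignment (for tiny inputs only).

    An alignment is a chain of aligned residue pairs with strictly
    increasing coordinates; the gap between consecutive pairs costs
    11 + k per run of skipped residues. Exponential: keep len <= 7.
    """

    def gap(k: int) -> float:
        return 0.0 if k == 0 else -(GAP_OPEN + k * GAP_EXTEND)

    @lru_cache(maxsize=None)
    def from_pair(i: int, j: int) -> float:
        base = blosum(q[i], t[j])
        best_ext = 0.0
        for i2 in range(i + 1, len(q)):
            for j2 in range(j + 1, len(t)):
                ext = (gap(i2 - i - 1) + gap(j2 - j - 1) + from_pair(i2, j2))
                best_ext = max(best_ext, ext)
        return base + best_ext

    best = 0.0
    for i in range(len(q)):
        for j in range(len(t)):
            best = max(best, from_pair(i, j))
    from_pair.cache_clear()
    return best


def sam_d_direct(values, s0: float):
    """One-gene SAM statistic computed straight from the formula."""
    import statistics

    n = len(values)
    mean = sum(values) / n
    sd = statistics.stdev(values) if n > 1 else float("nan")
    s = sd / n ** 0.5
    return mean / (s + s0), s
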