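"""Independent reference implementations used as test oracles."""

import math

import numpy as np

NEG = float("-inf")


def gotoh_local_score(a, b, match=2.0, mismatch=-3.0, gap_open=7.0, gap_extend=2.0):
    """Affine-gap Smith-Waterman best score; quadratic reference DP.

    ``gap_open`` is the cost of the first gapped position (open + extend in
    the open/extend parameterization), matching the aligner configuration.
    """
    n, m = len(a), len(b)
    M = np.zeros((n + 1, m + 1))
    X = np.full((n + 1, m + 1), NEG)
    Y = np.full((n + 1, m + 1), NEG)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            diag = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1], 0.0)
            M[i][j] = diag + s
            X[i][j] = max(M[i - 1][j] - gap_open, X[i - 1][j] - gap_extend)
            Y[i][j] = max(M[i][j - 1] - gap_open, Y[i][j - 1] - gap_extend)
            best = max(best, M[i][j], X[i][j], Y[i][j])
    return best


def hypergeom_upper_tail_exact(k, K, n, N):
    """P(X >= k) by direct summation of binomial-coefficient ratios."""
    denom = math.comb(N, n)
    return sum(
        math.comb(K, i) * math.comb(N - K, n - i) for i in range(k, min(K, n) + 1)
    ) / denom


def brute_union_length(intervals):
    covered = set()
    for start, end in intervals:
        covered.update(range(start, end))
    return len(covered)
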