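"""Shared fixtures and independent oracles used across the test suite.

The oracles here deliberately re-derive results by brute force (exhaustive
enumeration, quadratic DP) so the implementation under test is checked
against an independent computation path, never against itself.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest


def brute_force_1d_transport(x: np.ndarray, r: np.ndarray) -> float:
    """Min-cost assignment between two equal-size 1-D multisets, |.| cost.

    Exhaustive search over all M! pairings; only usable for tiny M.
    """
    x = np.asarray(x, dtype=float)
    r = np.asarray(r, dtype=float)
    assert x.size == r.size <= 6
    best = np.inf
    for perm in itertools.permutations(range(r.size)):
        cost = float(np.sum(np.abs(x - r[list(perm)])))
        best = min(best, cost)
    return best


def wilcoxon_enumeration_p(diffs: np.ndarray) -> float:
    """Two-sided exact signed-rank p by enumerating all 2^n sign patterns."""
    from scipy.stats import rankdata

    d = np.asarray(diffs, dtype=float)
    d = d[d != 0.0]
    assert d.size >= 1
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    sums = []
    for signs in itertools.product([0, 1], repeat=d.size):
        sums.append(np.dot(signs, ranks))
    sums = np.asarray(sums)
    n_total = sums.size
    p_le = np.sum(sums <= w_obs + 1e-12) / n_total
    p_ge = np.sum(sums >= w_obs - 1e-12) / n_total
    return min(1.0, 2.0 * min(p_le, p_ge))


def gotoh_score(seq_a: str, seq_b: str, matrix, gap_open: float, gap_extend: float) -> float:
    """Quadratic-time affine-gap global alignment score (end gaps penalized).

    A gap of length L costs gap_open + (L - 1) * gap_extend.  Independent of
    the aligner used by the package.
    """
    n, m = len(seq_a), len(seq_b)
    neg = -np.inf
    M = np.full((n + 1, m + 1), neg)
    Ix = np.full((n + 1, m + 1), neg)  # gap in seq_b (consumes seq_a)
    Iy = np.full((n + 1, m + 1), neg)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        Ix[i, 0] = -(gap_open + (i - 1) * gap_extend)
    for j in range(1, m + 1):
        Iy[0, j] = -(gap_open + (j - 1) * gap_extend)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = matrix[seq_a[i - 1], seq_b[j - 1]]
            M[i, j] = s + max(M[i - 1, j - 1], Ix[i - 1, j - 1], Iy[i - 1, j - 1])
            Ix[i, j] = max(M[i - 1, j] - gap_open, Ix[i - 1, j] - gap_extend)
            Iy[i, j] = max(M[i, j - 1] - gap_open, Iy[i, j - 1] - gap_extend)
    return float(max(M[n, m], Ix[n, m], Iy[n, m]))


def ols_closed_form(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-parameter regression slope/intercept from the normal equations."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xbar, ybar = x.mean(), y.mean()
    slope = np.sum((x - xbar) * (y - ybar)) / np.sum((x - xbar) ** 2)
    return float(slope), float(ybar - slope * xbar)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
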