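"""Independent oracles used by the test suite.

These are deliberately naive recomputations (explicit nested windows, direct
tail summation) that share no code path with the package implementation.
"""

from __future__ import annotations

import math

from prionscan.scoring import (
    FOLDINDEX_CHARGE,
    FOLDINDEX_COEFFICIENTS,
    FOLDINDEX_HYDROPHOBICITY,
)


def brute_position_scores(sequence, propensity, window_size=41):
    """Per-position (position, raw_score, foldindex) by explicit nested
    windows: every governing full window recomputed from scratch."""
    w = window_size
    L = len(sequence)
    if L < w:
        return []
    pv = [propensity[aa] for aa in sequence]
    hv = [FOLDINDEX_HYDROPHOBICITY[aa] for aa in sequence]
    cv = [FOLDINDEX_CHARGE[aa] for aa in sequence]
    slope, intercept = FOLDINDEX_COEFFICIENTS
    out = []
    for p in range(L):
        first = max(0, p - w + 1)
        last = min(p, L - w)
        window_means = []
        for j in range(first, last + 1):
            window_means.append(sum(pv[j : j + w]) / w)
        raw = sum(window_means) / len(window_means)
        span = slice(first, last + w)
        n = (last + w) - first
        mh = sum(hv[span]) / n
        mc = sum(cv[span]) / n
        fi = slope * mh - abs(mc) + intercept
        out.append((p + 1, raw, fi))
    return out


def brute_protein_score(sequence, propensity, window_size=41, sentinel=-1.0):
    gated = [
        raw
        for _, raw, fi in brute_position_scores(sequence, propensity, window_size)
        if fi < 0
    ]
    return max(gated) if gated else sentinel


def fisher_two_sided_p(a, b, c, d):
    """Two-sided Fisher exact p by exhaustive hypergeometric tail summation:
    sum of the probabilities of all tables (same margins) whose point
    probability does not exceed that of the observed table."""
    row1 = a + b
    row2 = c + d
    col1 = a + c
    n = row1 + row2

    def pmf(k):
        return (
            math.comb(row1, k)
            * math.comb(row2, col1 - k)
            / math.comb(n, col1)
        )

    k_min = max(0, col1 - row2)
    k_max = min(col1, row1)
    p_obs = pmf(a)
    total = 0.0
    for k in range(k_min, k_max + 1):
        pk = pmf(k)
        if pk <= p_obs * (1 + 1e-12):
            total += pk
    return min(total, 1.0)


def bh_step_up(pvalues):
    """Benjamini-Hochberg q-values by the textbook step-up recursion."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    q = [0.0] * m
    prev = 1.0
    for rank_from_end, idx in enumerate(reversed(order)):
        rank = m - rank_from_end
        val = min(prev, pvalues[idx] * m / rank)
        q[idx] = val
        prev = val
    return q
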