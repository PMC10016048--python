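"""Independent reference implementations used as test oracles.

These deliberately avoid the code paths they check: DTW by exhaustive
warping-path enumeration, and the two-stage step-up FDR written directly
from its definition.
"""

import numpy as np


def dtw_bruteforce(a, b):
    """Minimum cost over all boundary-anchored monotone warping paths."""
    m, n = len(a), len(b)

    def cost(i, j):
        return np.linalg.norm(a[i] - b[j])

    best = [np.inf]

    def walk(i, j, acc):
        if acc >= best[0]:
            return
        if i == m - 1 and j == n - 1:
            best[0] = acc
            return
        for di, dj in ((1, 0), (0, 1), (1, 1)):
            ii, jj = i + di, j + dj
            if ii < m and jj < n:
                walk(ii, jj, acc + cost(ii, jj))

    walk(0, 0, cost(0, 0))
    return best[0]


def bky_reference(p, q=0.05):
    """Two-stage step-up FDR from its textbook definition."""
    p = np.asarray(p, float)
    m = len(p)

    def bh(pvals, level):
        order = np.argsort(pvals)
        sorted_p = pvals[order]
        thresh = level * np.arange(1, m + 1) / m
        below = np.flatnonzero(sorted_p <= thresh)
        mask = np.zeros(m, bool)
        if below.size:
            mask[order[: below.max() + 1]] = True
        return mask

    q1 = q / (1.0 + q)
    r1 = bh(p, q1).sum()
    if r1 == 0:
        return np.zeros(m, bool)
    if r1 == m:
        return np.ones(m, bool)
    return bh(p, q1 * m / (m - r1))
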