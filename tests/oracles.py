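"""Independent brute-force oracles used by the test suite.

These are deliberately naive implementations — exhaustive enumeration and
direct tail summation — kept separate from the package so they can serve as
ground truth for the fast paths.
"""

import itertools
import math

import numpy as np


def bh_stepup(pvalues):
    """Benjamini-Hochberg step-up adjustment, straight from the definition."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


def signed_rank_exact_p(differences, alternative="two-sided"):
    """Exact signed-rank p by enumeration of all 2^n sign assignments.

    Differences must be nonzero and tie-free in absolute value.
    """
    d = np.asarray(differences, dtype=float)
    assert (d != 0).all()
    absd = np.abs(d)
    assert len(set(absd)) == len(absd), "tie-free magnitudes required"
    ranks = np.argsort(np.argsort(absd)) + 1
    w_obs = ranks[d > 0].sum()
    n = len(d)
    ws = []
    for signs in itertools.product([0, 1], repeat=n):
        ws.append(sum(r for r, s in zip(ranks, signs) if s))
    ws = np.asarray(ws, dtype=float)
    total = len(ws)
    if alternative == "greater":
        return (ws >= w_obs).sum() / total
    if alternative == "less":
        return (ws <= w_obs).sum() / total
    lo = (ws <= w_obs).sum() / total
    hi = (ws >= w_obs).sum() / total
    return min(1.0, 2.0 * min(lo, hi))


def hypergeom_tail_p(overlap, n_signature, n_reference, n_universe):
    """P(X >= overlap) for X hypergeometric, by direct summation."""
    total = 0.0
    denom = math.comb(n_universe, n_signature)
    for k in range(overlap, min(n_signature, n_reference) + 1):
        total += math.comb(n_reference, k) * math.comb(n_universe - n_reference, n_signature - k)
    return total / denom
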