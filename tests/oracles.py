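"""Independent reference implementations used only to check the package.

Everything here is deliberately naive — exhaustive enumeration, direct
dynamic programming, positional comparison — and shares no code with the
implementation under test.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction

import numpy as np

NEG = float("-inf")


def positional_identity(a: str, b: str) -> float:
    """Percent identity of two equal-length, gap-free sequences."""
    assert len(a) == len(b) and a
    return 100.0 * sum(x == y for x, y in zip(a, b)) / len(a)


def gotoh_semiglobal_score(a: str, b: str, score_fn, gap_open: float,
                           gap_extend: float) -> float:
    """Optimal semi-global alignment score, affine gaps, free end gaps.

    The first residue of a gap costs ``gap_open``; each further residue
    ``gap_extend``.  Terminal overhangs are free.  Direct three-state
    dynamic programming; quadratic and only meant for tiny inputs.
    """
    la, lb = len(a), len(b)
    M = [[NEG] * (lb + 1) for _ in range(la + 1)]
    X = [[NEG] * (lb + 1) for _ in range(la + 1)]  # gap in b, consumes a
    Y = [[NEG] * (lb + 1) for _ in range(la + 1)]  # gap in a, consumes b
    lead = [[NEG] * (lb + 1) for _ in range(la + 1)]
    for i in range(la + 1):
        lead[i][0] = 0.0
    for j in range(lb + 1):
        lead[0][j] = 0.0
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            s = score_fn(a[i - 1], b[j - 1])
            M[i][j] = s + max(M[i - 1][j - 1], X[i - 1][j - 1],
                              Y[i - 1][j - 1], lead[i - 1][j - 1])
            X[i][j] = max(M[i - 1][j] + gap_open, X[i - 1][j] + gap_extend,
                          Y[i - 1][j] + gap_open, lead[i - 1][j] + gap_open)
            Y[i][j] = max(M[i][j - 1] + gap_open, Y[i][j - 1] + gap_extend,
                          X[i][j - 1] + gap_open, lead[i][j - 1] + gap_open)
    best = 0.0  # the all-overhang arrangement aligns nothing and scores 0
    for i in range(la + 1):
        best = max(best, M[i][lb], X[i][lb], Y[i][lb])
    for j in range(lb + 1):
        best = max(best, M[la][j], X[la][j], Y[la][j])
    return best


def connected_components(nodes, edge_fn):
    """Components of the graph {(u, v): edge_fn(u, v)} by direct BFS."""
    nodes = list(nodes)
    unseen = set(nodes)
    comps = []
    while unseen:
        start = unseen.pop()
        comp = {start}
        frontier = [start]
        while frontier:
            u = frontier.pop()
            for v in list(unseen):
                if edge_fn(u, v):
                    unseen.discard(v)
                    comp.add(v)
                    frontier.append(v)
        comps.append(frozenset(comp))
    return set(comps)


def hypergeom_tail_exact(k: int, n: int, K: int, N: int) -> Fraction:
    """P(X >= k) by exact rational term-by-term enumeration."""
    total = math.comb(N, n)
    acc = Fraction(0)
    for x in range(k, min(n, K) + 1):
        acc += Fraction(math.comb(K, x) * math.comb(N - K, n - x), total)
    return acc


def exhaustive_rarefaction(presence: np.ndarray):
    """Mean pan sizes and new-family counts over all G! genome orders."""
    G = presence.shape[0]
    pans, news = [], []
    for order in itertools.permutations(range(G)):
        seen = np.zeros(presence.shape[1], dtype=bool)
        pan_row, new_row = [], []
        for gi in order:
            new_row.append(int((presence[gi] & ~seen).sum()))
            seen |= presence[gi]
            pan_row.append(int(seen.sum()))
        pans.append(pan_row)
        news.append(new_row)
    return np.mean(pans, axis=0), np.mean(news, axis=0)


def expected_new_counts(presence: np.ndarray) -> np.ndarray:
    """Closed-form E[new families at step N] under uniform random orders.

    A family carried by c of G genomes is first seen at step N with
    probability C(G-c, N-1)/C(G, N-1) - C(G-c, N)/C(G, N).
    """
    G = presence.shape[0]
    carriers = presence.sum(axis=0)
    out = np.zeros(G)
    for N in range(1, G + 1):
        acc = Fraction(0)
        for c in carriers:
            p_prev = Fraction(math.comb(G - int(c), N - 1), math.comb(G, N - 1))
            p_now = Fraction(math.comb(G - int(c), N), math.comb(G, N)) \
                if G - int(c) >= N else Fraction(0)
            acc += p_prev - p_now
        out[N - 1] = float(acc)
    return out


def loglog_powerlaw_fit(steps, counts):
    """Closed-form least squares of log(counts) on log(steps)."""
    x = np.log(np.asarray(steps, dtype=float))
    y = np.log(np.asarray(counts, dtype=float))
    xbar, ybar = x.mean(), y.mean()
    slope = ((x - xbar) * (y - ybar)).sum() / ((x - xbar) ** 2).sum()
    intercept = ybar - slope * xbar
    return math.exp(intercept), -slope  # kappa, alpha
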