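"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths they check: the rank-sum oracle
enumerates label assignments with itertools, the Fisher oracle sums
hypergeometric point masses, and the layer oracle recomputes degrees
straight from a raw edge list.
"""

import itertools
import math

import numpy as np


def u_pairs(x, y):
    """U of x by direct pair counting (ties count half)."""
    return sum(
        (1.0 if xi > yi else 0.5 if xi == yi else 0.0) for xi in x for yi in y
    )


def enum_ranksum_p(x, y, tail):
    """Exact rank-sum p by enumerating all C(n, nx) label assignments."""
    pooled = list(x) + list(y)
    n, nx = len(pooled), len(x)
    obs = u_pairs(x, y)
    us = []
    for idx in itertools.combinations(range(n), nx):
        chosen = set(idx)
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(n) if i not in chosen]
        us.append(u_pairs(xs, ys))
    us = np.asarray(us)
    eps = 1e-9
    p_ge = float(np.mean(us >= obs - eps))
    p_le = float(np.mean(us <= obs + eps))
    if tail == "greater":
        return p_ge
    if tail == "less":
        return p_le
    return min(1.0, 2.0 * min(p_ge, p_le))


def hypergeom_pmf(a, row1, row2, col1):
    n = row1 + row2
    return (
        math.comb(row1, a) * math.comb(row2, col1 - a) / math.comb(n, col1)
    )


def enum_fisher_p(a, b, c, d, tail="two-sided"):
    """Fisher p by full enumeration over the free cell of the 2x2 table."""
    row1, row2, col1 = a + b, c + d, a + c
    lo, hi = max(0, col1 - row2), min(row1, col1)
    pmf = {k: hypergeom_pmf(k, row1, row2, col1) for k in range(lo, hi + 1)}
    obs = pmf[a]
    if tail == "greater":
        return sum(v for k, v in pmf.items() if k >= a)
    if tail == "less":
        return sum(v for k, v in pmf.items() if k <= a)
    return min(1.0, sum(v for v in pmf.values() if v <= obs * (1 + 1e-9)))


def brute_force_layers(edges, nodes, scheme):
    """Recompute layer labels from the raw edge list alone."""
    edge_set = set()
    for u, v in edges:
        if u != v:
            edge_set.add((u, v))
    labels = {}
    for n in nodes:
        out_d = sum(1 for u, v in edge_set if u == n)
        in_d = sum(1 for u, v in edge_set if v == n)
        if scheme == "simple":
            if out_d > 0 and in_d == 0:
                labels[n] = "TOP"
            elif out_d > 0 and in_d > 0:
                labels[n] = "MID"
            elif in_d > 0:
                labels[n] = "BOT"
            else:
                labels[n] = "OUTGROUP"
        else:
            if out_d >= 2 and in_d <= 1:
                labels[n] = "TOP"
            elif out_d >= 2:
                labels[n] = "MID"
            elif in_d >= 2:
                labels[n] = "BOT"
            else:
                labels[n] = "OUTGROUP"
    return labels
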