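"""Independent brute-force oracles used to cross-check the implementation.

Each is deliberately naive: dense arrays, explicit loops, direct
definitions, no code shared with the package.
"""

from itertools import combinations
from math import comb

import numpy as np


def em_oracle(entries, n_frag, n_loci, theta_prior, lam=0.1, iters=10_000):
    """Dense-matrix MAP EM run to a fixed large iteration count."""
    W = np.zeros((n_frag, n_loci))
    member = np.zeros((n_frag, n_loci), dtype=bool)
    best = {}
    for f, _l, s in entries:
        best[f] = max(best.get(f, -np.inf), s)
    for f, l, s in entries:
        member[f, l] = True
        W[f, l] = np.exp(lam * (s - best[f]))
    theta = theta_prior / n_loci
    pi = np.ones(n_loci) / n_loci
    for _ in range(iters):
        R = pi[None, :] * W * member
        R = R / R.sum(axis=1, keepdims=True)
        pi = R.sum(axis=0) + theta
        pi = pi / pi.sum()
    return pi


def bh_oracle(p):
    """Literal step-up definition: q_(i) = min_{j >= i} m p_(j) / j."""
    p = list(p)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    for rank_pos, i in enumerate(order, start=1):
        q[i] = min(
            min(m * p[order[j - 1]] / j for j in range(rank_pos, m + 1)), 1.0
        )
    return q


def median_of_ratios_oracle(x):
    """Direct median-of-ratios size factors over all-positive features."""
    x = np.asarray(x, dtype=float)
    keep = (x > 0).all(axis=1)
    ref = x[keep]
    geo = np.array([np.prod(row) ** (1.0 / len(row)) for row in ref])
    return np.array(
        [np.median(ref[:, j] / geo) for j in range(x.shape[1])]
    )


def mannwhitney_exact_oracle(x, y):
    """Exact two-sided Mann-Whitney p by full enumeration of group
    assignments (small samples, no tie correction shortcuts)."""
    pooled = list(x) + list(y)
    n1 = len(x)
    idx = range(len(pooled))

    def u_stat(group1):
        g1 = [pooled[i] for i in group1]
        g2 = [pooled[i] for i in idx if i not in set(group1)]
        u = 0.0
        for a in g1:
            for b in g2:
                if a > b:
                    u += 1.0
                elif a == b:
                    u += 0.5
        return u

    obs = u_stat(tuple(range(n1)))
    n = len(pooled)
    mean_u = n1 * (len(y)) / 2.0
    count = 0
    total = 0
    for group1 in combinations(idx, n1):
        u = u_stat(group1)
        if abs(u - mean_u) >= abs(obs - mean_u) - 1e-12:
            count += 1
        total += 1
    return count / total


def fisher_exact_oracle(table):
    """Two-sided Fisher p by enumerating all tables with the same margins
    and summing probabilities <= the observed table's."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(a_):
        b_, c_ = r1 - a_, c1 - a_
        d_ = r2 - c_
        if min(b_, c_, d_) < 0:
            return None
        return comb(r1, a_) * comb(r2, c_) / comb(n, c1)

    p_obs = prob(a)
    total = 0.0
    for a_ in range(0, min(r1, c1) + 1):
        p = prob(a_)
        if p is not None and p <= p_obs * (1 + 1e-9):
            total += p
    return total


def hypergeom_sf_oracle(k, n_universe, n_set, n_draw):
    """P(X >= k) for X ~ Hypergeom by direct summation."""
    total = 0.0
    for x in range(k, min(n_set, n_draw) + 1):
        total += (
            comb(n_set, x) * comb(n_universe - n_set, n_draw - x) / comb(n_universe, n_draw)
        )
    return total


def rank_sum_exact_oracle(member_scores, bg_scores):
    """Exact two-sided rank-sum p via enumeration (alias with explicit
    naming for the enrichment tests)."""
    return mannwhitney_exact_oracle(member_scores, bg_scores)


def ols_oracle(y, x):
    """Hand-formula simple regression: beta, se, two-sided t p-value."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    xb, yb = x.mean(), y.mean()
    sxx = ((x - xb) ** 2).sum()
    beta = ((x - xb) * (y - yb)).sum() / sxx
    alpha = yb - beta * xb
    resid = y - alpha - beta * x
    s2 = (resid**2).sum() / (n - 2)
    se = np.sqrt(s2 / sxx)
    from scipy.stats import t as tdist

    tval = beta / se
    p = 2 * tdist.sf(abs(tval), n - 2)
    return beta, se, p
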