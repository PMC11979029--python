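"""Brute-force reference implementations used only by the test suite.

These are deliberately naive (enumeration, pair counting, definitional
step-up) and independent of the library code paths they check.
"""

from itertools import combinations, permutations

import numpy as np


def u_statistic(x, y):
    """Mann-Whitney U for x by direct pair counting."""
    u = 0.0
    for xi in x:
        for yj in y:
            if xi > yj:
                u += 1.0
            elif xi == yj:
                u += 0.5
    return u


def exact_ranksum_p(x, y):
    """Two-sided exact p by enumerating all group labelings of the pooled
    sample (tie-free inputs): P(|U - mu| >= |U_obs - mu|)."""
    pooled = list(x) + list(y)
    n1 = len(x)
    mu = n1 * len(y) / 2.0
    obs = abs(u_statistic(x, y) - mu)
    hits = total = 0
    for idx in combinations(range(len(pooled)), n1):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(len(pooled)) if i not in idx]
        total += 1
        if abs(u_statistic(xs, ys) - mu) >= obs - 1e-12:
            hits += 1
    return hits / total


def bh_stepup(p_values, q):
    """Definitional BH: largest k with p_(k) <= k*q/m; reject those k."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    k_star = 0
    for k in range(1, m + 1):
        if p[order[k - 1]] <= k * q / m:
            k_star = k
    reject = np.zeros(m, dtype=bool)
    reject[order[:k_star]] = True
    return reject


def auc_pairs(scores, labels):
    """AUC by explicit positive-negative pair counting."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = ties = 0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1
            elif p == n:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


def spearman_formula(x, y):
    """1 - 6*sum(d^2)/(n(n^2-1)) on tie-free data."""
    from scipy.stats import rankdata

    rx, ry = rankdata(x), rankdata(y)
    d = rx - ry
    n = len(x)
    return 1 - 6 * float(d @ d) / (n * (n**2 - 1))


def spearman_perm_p(x, y):
    """Exact two-sided permutation p of |rho| (n <= 8 practical)."""
    obs = abs(spearman_formula(x, y))
    hits = total = 0
    for perm in permutations(y):
        total += 1
        if abs(spearman_formula(x, perm)) >= obs - 1e-12:
            hits += 1
    return hits / total
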