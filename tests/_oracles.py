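"""Independent oracles used by the test suite.

These deliberately take the slow, obviously-correct route (enumeration,
quadratic dynamic programming) and share no code with the implementation
paths they check.
"""

from itertools import combinations, product

import numpy as np

GENOTYPES = [(0, 0), (0, 1), (1, 1)]


def enumerate_phase(father, mother, offspring):
    """Brute-force transmission phase of one genotype triple.

    Tries every (paternal, maternal) allele assignment drawn from the
    parents' genotypes; returns ('phased', (p, m)), ('undetermined', None)
    or ('violation', None).
    """
    target = sorted(offspring)
    found = set()
    for p, m in product(father, mother):
        if sorted((p, m)) == target:
            found.add((p, m))
    if not found:
        return "violation", None
    if len(found) > 1:
        return "undetermined", None
    return "phased", found.pop()


def all_genotype_triples():
    return list(product(GENOTYPES, GENOTYPES, GENOTYPES))


def bernoulli_nll(k, m):
    cost = 0.0
    if 0 < k:
        cost -= k * np.log(k / m)
    if k < m:
        cost -= (m - k) * np.log(1 - k / m)
    return cost


def penalized_cost(x, changepoints, beta=3.0):
    x = np.asarray(x, dtype=float)
    n = len(x)
    bounds = [0, *sorted(changepoints), n]
    total = len(changepoints) * beta * np.log(n)
    for a, b in zip(bounds[:-1], bounds[1:]):
        total += bernoulli_nll(x[a:b].sum(), b - a)
    return total


def exhaustive_segmentation(x, beta=3.0):
    """Minimum penalized cost over ALL 2^(n-1) boundary subsets (n small)."""
    n = len(x)
    assert n <= 14, "enumeration only feasible for short tracks"
    best_cost, best_cps, best_k = np.inf, [], 0
    for k in range(0, n):
        improved = False
        for cps in combinations(range(1, n), k):
            c = penalized_cost(x, cps, beta)
            if c < best_cost - 1e-12:
                best_cost, best_cps, best_k = c, list(cps), k
                improved = True
        if k > best_k + 1 and not improved:
            break
    return best_cps, best_cost


def full_dp_segmentation(x, beta=3.0):
    """Exact optimal partitioning over every site boundary, O(n^2), no
    run-length shortcut and no pruning."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    pen = beta * np.log(n)
    cs = np.concatenate(([0.0], np.cumsum(x)))
    F = np.full(n + 1, np.inf)
    F[0] = -pen
    ncp = np.zeros(n + 1, dtype=int)
    prev = np.zeros(n + 1, dtype=int)
    for t in range(1, n + 1):
        best, bncp, bs = np.inf, -1, 0
        for s in range(t):
            f = F[s] + bernoulli_nll(cs[t] - cs[s], t - s) + pen
            if f < best - 1e-12 or (f < best + 1e-12 and ncp[s] + 1 < bncp):
                best, bncp, bs = f, ncp[s] + 1, s
        F[t], ncp[t], prev[t] = best, bncp, bs
    cps = []
    t = n
    while t > 0:
        s = prev[t]
        if s > 0:
            cps.append(s)
        t = s
    return sorted(cps), F[n]
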