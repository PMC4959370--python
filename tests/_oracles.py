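"""Independent brute-force oracles used by the test suite.

Everything here is written as plain loops from the textbook definitions,
deliberately sharing no code with the package, so agreement between the
two routes is meaningful.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy import stats


def logrank_oracle(ta, ea, tb, eb):
    """Two-sample log-rank chi-square by looping over the pooled distinct
    event times with the hypergeometric variance."""
    t = list(ta) + list(tb)
    e = list(ea) + list(eb)
    grp = [0] * len(ta) + [1] * len(tb)
    event_times = sorted({ti for ti, ei in zip(t, e) if ei == 1})
    O = E = V = 0.0
    for tau in event_times:
        at_risk = [i for i in range(len(t)) if t[i] >= tau]
        n = len(at_risk)
        n_a = sum(1 for i in at_risk if grp[i] == 0)
        deaths = [i for i in at_risk if t[i] == tau and e[i] == 1]
        d = len(deaths)
        d_a = sum(1 for i in deaths if grp[i] == 0)
        O += d_a
        E += d * n_a / n
        if n > 1:
            V += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
    if V == 0:
        return 0.0, 1.0
    chi2 = (O - E) ** 2 / V
    return chi2, float(stats.chi2.sf(chi2, 1))


def km_oracle(times, events):
    """Product-limit estimate by hand: dict event_time -> S(t+)."""
    out = {}
    s = 1.0
    for tau in sorted({ti for ti, ei in zip(times, events) if ei == 1}):
        n = sum(1 for ti in times if ti >= tau)
        d = sum(1 for ti, ei in zip(times, events) if ti == tau and ei == 1)
        s *= 1 - d / n
        out[tau] = s
    return out


def cox_partial_loglik(beta, t, e, x):
    """Efron-tie Cox partial log-likelihood for a binary covariate,
    computed subject-by-subject."""
    ll = 0.0
    for tau in sorted({ti for ti, ei in zip(t, e) if ei == 1}):
        risk = [i for i in range(len(t)) if t[i] >= tau]
        deaths = [i for i in risk if t[i] == tau and e[i] == 1]
        d = len(deaths)
        s_risk = sum(np.exp(beta * x[i]) for i in risk)
        s_d = sum(np.exp(beta * x[i]) for i in deaths)
        ll += sum(beta * x[i] for i in deaths)
        for l in range(d):
            ll -= np.log(s_risk - (l / d) * s_d)
    return ll


def cox_hr_grid_oracle(ta, ea, tb, eb, lo=-8.0, hi=8.0, n_coarse=2001):
    """HR of group A vs B by maximizing the partial likelihood on a fine
    beta grid, then a local refinement."""
    t = list(ta) + list(tb)
    e = list(ea) + list(eb)
    x = [1] * len(ta) + [0] * len(tb)
    grid = np.linspace(lo, hi, n_coarse)
    lls = [cox_partial_loglik(b, t, e, x) for b in grid]
    b0 = grid[int(np.argmax(lls))]
    fine = np.linspace(b0 - 0.02, b0 + 0.02, 801)
    lls = [cox_partial_loglik(b, t, e, x) for b in fine]
    return float(np.exp(fine[int(np.argmax(lls))]))


def bh_oracle(p):
    """Benjamini-Hochberg step-up: adj_i = min over ranks j >= rank(i) of
    p_(j) * m / j, capped at 1."""
    p = list(p)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [None] * m
    running = 1.0
    for k in range(m - 1, -1, -1):
        i = order[k]
        running = min(running, p[i] * m / (k + 1))
        adj[i] = running
    return adj


def max_cliques_bruteforce(nodes, edges):
    """All maximum cliques of a small graph by subset enumeration."""
    nodes = sorted(nodes)
    eset = {frozenset(e) for e in edges}
    best = []
    best_k = 0
    for r in range(1, len(nodes) + 1):
        found = False
        for comb in itertools.combinations(nodes, r):
            if all(frozenset((u, v)) in eset
                   for u, v in itertools.combinations(comb, 2)):
                found = True
                if r > best_k:
                    best, best_k = [set(comb)], r
                elif r == best_k:
                    best.append(set(comb))
        if not found and r > 1:
            break
    return best_k, best


def max_edge_biclique_bruteforce(left, right, edges):
    """Best |A|x|B| bi-clique by enumerating subsets of the left side:
    for each non-empty A, B = common neighbours of A, which covers every
    maximal bi-clique.  Tie-break: larger min side, then lexicographic."""
    left = sorted(left)
    right = sorted(right)
    nbr = {u: {v for (a, v) in edges if a == u} | {v for (v, a) in edges if a == u}
           for u in left}
    best = ((), ())
    best_key = (0, 0)
    for r in range(1, len(left) + 1):
        for A in itertools.combinations(left, r):
            B = set(right)
            for u in A:
                B &= nbr[u]
            if not B:
                continue
            # expand A to all left nodes adjacent to every member of B
            # (maximality on the left side)
            A_full = tuple(sorted(u for u in left if B <= nbr[u]))
            Bt = tuple(sorted(B))
            key = (len(A_full) * len(Bt), min(len(A_full), len(Bt)))
            cand = (A_full, Bt)
            if key > best_key or (key == best_key and cand < best):
                best, best_key = cand, key
    return best
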