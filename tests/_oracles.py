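"""Independent brute-force oracles used by the test suite.

Each oracle recomputes a p-value from first principles (integer
hypergeometric weights, full permutation enumeration) through code paths
disjoint from the package's implementations.
"""

import itertools
from math import comb

import numpy as np
from scipy import stats


def fisher_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by exact integer hypergeometric enumeration:
    total probability of tables (at fixed margins) whose integer weight
    C(r1,x)*C(r2,c1-x) does not exceed the observed table's weight."""
    r1, r2, c1 = a + b, c + d, a + c
    amin, amax = max(0, c1 - r2), min(r1, c1)
    ws = [comb(r1, x) * comb(r2, c1 - x) for x in range(amin, amax + 1)]
    w_obs = ws[a - amin]
    return sum(w for w in ws if w <= w_obs) / sum(ws)


def friedman_permutation_oracle(mat: np.ndarray) -> float:
    """Exact Friedman p by enumerating all (k!)^n within-block orderings of
    the observed values, scoring each with scipy's Friedman statistic."""
    mat = np.asarray(mat, dtype=float)
    n, k = mat.shape
    stat_obs = stats.friedmanchisquare(*mat.T).statistic
    perms = list(itertools.permutations(range(k)))
    hits = total = 0
    for assignment in itertools.product(perms, repeat=n):
        pm = np.stack([mat[i, list(p)] for i, p in enumerate(assignment)])
        total += 1
        if stats.friedmanchisquare(*pm.T).statistic >= stat_obs - 1e-9:
            hits += 1
    return hits / total


def signed_rank_sign_flip_oracle(diffs) -> float:
    """Exact two-sided signed-rank p by enumerating every sign assignment of
    the nonzero differences."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    r = stats.rankdata(np.abs(d))
    mu = r.sum() / 2.0
    w_obs = r[d > 0].sum()
    hits = total = 0
    for signs in itertools.product((0.0, 1.0), repeat=len(d)):
        w = float(np.dot(signs, r))
        total += 1
        if abs(w - mu) >= abs(w_obs - mu) - 1e-9:
            hits += 1
    return hits / total


def rank_sum_enumeration_oracle(x, y) -> float:
    """Exact two-sided rank-sum p by enumerating all group assignments."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    n1 = len(x)
    mu = n1 * (len(pooled) + 1) / 2.0
    w_obs = ranks[:n1].sum()
    hits = total = 0
    for comb_idx in itertools.combinations(range(len(pooled)), n1):
        w = ranks[list(comb_idx)].sum()
        total += 1
        if abs(w - mu) >= abs(w_obs - mu) - 1e-9:
            hits += 1
    return hits / total
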