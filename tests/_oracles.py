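"""Independent brute-force oracles used by the statistical tests.

Everything here is written from the definition of the statistic (explicit
enumeration or an explicit min-over-suffix loop), deliberately sharing no
code with the package implementations it checks.
"""

import itertools
import math

import numpy as np
from scipy.stats import rankdata


def bh_oracle(p):
    """Benjamini-Hochberg by the explicit min-over-suffix definition."""
    p = list(p)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [None] * m
    for rank_pos, i in enumerate(order, start=1):
        candidates = []
        for rank_j, j in enumerate(order, start=1):
            if rank_j >= rank_pos:
                candidates.append(p[j] * m / rank_j)
        adj[i] = min(1.0, min(candidates))
    return adj


def mann_whitney_p_oracle(x, y):
    """Exact two-sided p by enumerating all C(n1+n2, n1) group assignments."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    r = rankdata(pooled)
    mid = n1 * len(y) / 2
    u_obs = r[:n1].sum() - n1 * (n1 + 1) / 2
    hits = total = 0
    for comb in itertools.combinations(range(len(pooled)), n1):
        u = r[list(comb)].sum() - n1 * (n1 + 1) / 2
        hits += abs(u - mid) >= abs(u_obs - mid) - 1e-9
        total += 1
    return hits / total


def wilcoxon_p_oracle(before, after):
    """Exact two-sided p by enumerating all 2^n sign assignments."""
    d = np.asarray(after, float) - np.asarray(before, float)
    d = d[d != 0]
    r = rankdata(np.abs(d))
    m = r.sum()
    w_obs = r[d > 0].sum()
    dist = np.array([
        sum(ri for ri, s in zip(r, signs) if s)
        for signs in itertools.product([0, 1], repeat=len(d))
    ])
    lo = min(w_obs, m - w_obs)
    hi = m - lo
    # when w_obs sits at the null midpoint the two tails overlap; cap at 1
    p = ((dist <= lo + 1e-9).sum() + (dist >= hi - 1e-9).sum()) / dist.size
    return min(1.0, p)


def spearman_p_oracle(x, y):
    """Exact two-sided permutation p, pure-python enumeration."""
    rx = list(rankdata(x))
    ry = list(rankdata(y))
    n = len(rx)

    def pearson(a, b):
        ma = sum(a) / n
        mb = sum(b) / n
        num = sum((ai - ma) * (bi - mb) for ai, bi in zip(a, b))
        den = math.sqrt(sum((ai - ma) ** 2 for ai in a)
                        * sum((bi - mb) ** 2 for bi in b))
        return num / den

    obs = abs(pearson(rx, ry))
    hits = total = 0
    for perm in itertools.permutations(ry):
        hits += abs(pearson(rx, list(perm))) >= obs - 1e-12
        total += 1
    return hits / total


def auc_oracle(score, labels):
    """AUC as the explicit pairwise P(pos > neg) + 0.5 P(tie)."""
    score = np.asarray(score, float)
    labels = np.asarray(labels)
    pos = score[labels == 1]
    neg = score[labels != 1]
    wins = ties = 0
    for a in pos:
        for b in neg:
            wins += a > b
            ties += a == b
    return (wins + 0.5 * ties) / (len(pos) * len(neg))
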