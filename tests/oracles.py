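"""Independent brute-force oracles used to verify the statistical primitives.

Deliberately naive: plain enumeration, hand-rolled rank arithmetic and
closed-form combinatorics only — no scipy/sklearn/statsmodels and no calls
into the package under test.
"""

from __future__ import annotations

import itertools
import math


def brute_ranks(values):
    """Average ranks (1-based) with ties shared, by direct comparison."""
    n = len(values)
    ranks = []
    for v in values:
        less = sum(1 for u in values if u < v)
        equal = sum(1 for u in values if u == v)
        ranks.append(less + (equal + 1) / 2.0)
    return ranks


def brute_pearson(x, y):
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / math.sqrt(sxx * syy)


def brute_spearman(x, y):
    return brute_pearson(brute_ranks(x), brute_ranks(y))


def brute_spearman_exact_p(x, y):
    """Exact two-sided permutation p for Spearman's rho."""
    obs = abs(brute_spearman(x, y))
    hits = total = 0
    for perm in itertools.permutations(y):
        total += 1
        if abs(brute_spearman(x, list(perm))) >= obs - 1e-12:
            hits += 1
    return hits / total


def brute_mwu(a, b):
    """U statistic of sample a and the exact two-sided p by enumeration."""
    u = 0.0
    for x in a:
        for y in b:
            u += 1.0 if x > y else (0.5 if x == y else 0.0)
    pooled = list(a) + list(b)
    n1 = len(a)
    null_us = []
    for idx in itertools.combinations(range(len(pooled)), n1):
        grp = [pooled[i] for i in idx]
        rest = [pooled[i] for i in range(len(pooled)) if i not in idx]
        uu = sum(1.0 if x > y else (0.5 if x == y else 0.0)
                 for x in grp for y in rest)
        null_us.append(uu)
    mean_u = n1 * (len(pooled) - n1) / 2.0
    obs_dev = abs(u - mean_u)
    p = sum(1 for uu in null_us if abs(uu - mean_u) >= obs_dev - 1e-12) / len(null_us)
    return u, p


def brute_bh(pvals):
    """BH step-up: q_i = min over j with p_(j) >= p_(i) of p_(j) * m / j."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    q_sorted = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, pvals[i] * m / rank)
        q_sorted[rank - 1] = running
    q = [0.0] * m
    for rank, i in enumerate(order):
        q[i] = q_sorted[rank]
    return q


def brute_logrank(times, events, groups):
    """Two-group log-rank chi-square from the hand O-E table."""
    death_times = sorted({t for t, e in zip(times, events) if e == 1})
    o_minus_e = 0.0
    var = 0.0
    for t in death_times:
        at_risk = [(ti, ei, gi) for ti, ei, gi in zip(times, events, groups)
                   if ti >= t]
        n = len(at_risk)
        n1 = sum(1 for ti, ei, gi in at_risk if gi == 1)
        d = sum(1 for ti, ei, gi in at_risk if ei == 1 and ti == t)
        d1 = sum(1 for ti, ei, gi in at_risk
                 if ei == 1 and ti == t and gi == 1)
        if n <= 1:
            continue
        e1 = d * n1 / n
        v = d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1) if n > 1 else 0.0
        o_minus_e += d1 - e1
        var += v
    return (o_minus_e ** 2) / var


def brute_hypergeom_upper(k, M, n, N):
    """P(X >= k) for X ~ Hypergeom(M, n, N), by direct summation."""
    total = math.comb(M, N)
    acc = 0
    for x in range(k, min(n, N) + 1):
        acc += math.comb(n, x) * math.comb(M - n, N - x)
    return acc / total


def brute_gsea_es(ordered_genes, scores, members, weight=1.0):
    """Running-sum walk for the weighted KS enrichment score."""
    nh = sum(1 for g in ordered_genes if g in members)
    nm = len(ordered_genes) - nh
    denom = sum(abs(s) ** weight for g, s in zip(ordered_genes, scores)
                if g in members)
    run = 0.0
    best = 0.0
    for g, s in zip(ordered_genes, scores):
        if g in members:
            run += abs(s) ** weight / denom
        else:
            run -= 1.0 / nm
        if abs(run) > abs(best):
            best = run
    return best


def brute_ssgsea(expr_one_sample, in_set, alpha=0.25):
    """Weighted-ECDF difference score for one sample (genes aligned)."""
    ranks = brute_ranks(expr_one_sample)
    order = sorted(range(len(ranks)), key=lambda i: -ranks[i])
    denom = sum(ranks[i] ** alpha for i in order if in_set[i])
    n_out = sum(1 for f in in_set if not f)
    p_in = p_out = 0.0
    score = 0.0
    for i in order:
        if in_set[i]:
            p_in += ranks[i] ** alpha / denom
        else:
            p_out += 1.0 / n_out
        score += p_in - p_out
    return score


def brute_auc(scores, labels):
    """Exhaustive positive/negative pair counting, ties one half."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            wins += 1.0 if p > q else (0.5 if p == q else 0.0)
    return wins / (len(pos) * len(neg))
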