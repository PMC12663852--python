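"""Independent brute-force oracles used by the test suite.

Every function here is written from the definition of the quantity it
computes -- exhaustive enumeration, double loops, exact rational
arithmetic -- and deliberately shares no code with the package.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction

import numpy as np


def threshold_split_oracle(x):
    """Exhaustive minimum-within-SS split of a 1-D vector into two groups.

    Returns ``(labels, candidate_ss, unique)`` where ``labels`` marks the
    upper group of the best of the n-1 sorted threshold splits,
    ``candidate_ss`` lists the within-SS of every candidate, and
    ``unique`` says whether the optimum is unique (to fp tolerance).
    """
    x = np.asarray(x, dtype=float)
    xs = np.sort(x)
    candidates = []
    for i in range(1, len(xs)):
        lo, hi = xs[:i], xs[i:]
        candidates.append(
            float(((lo - lo.mean()) ** 2).sum() + ((hi - hi.mean()) ** 2).sum())
        )
    candidates = np.array(candidates)
    j = int(np.argmin(candidates))
    boundary = 0.5 * (xs[j] + xs[j + 1])
    labels = (x > boundary).astype(int)
    ordered = np.sort(candidates)
    unique = (ordered[1] - ordered[0]) > 1e-9 * max(1.0, abs(ordered[0]))
    return labels, candidates, unique


def _avg_ranks(values):
    """Ascending average ranks computed by explicit tie groups."""
    values = list(values)
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def ssgsea_oracle(column, gene_ids, set_genes, alpha):
    """Direct double-loop running-sum enrichment score for one sample."""
    vals = list(map(float, column))
    ids = list(gene_ids)
    ranks = _avg_ranks(vals)
    order = sorted(range(len(ids)), key=lambda i: (-vals[i], ids[i]))
    in_set = [ids[i] in set_genes for i in order]
    weights = [ranks[order[i]] ** alpha if in_set[i] else 0.0 for i in range(len(ids))]
    total_in = sum(weights)
    n_out = sum(1 for b in in_set if not b)
    es = 0.0
    cum_in = 0.0
    cum_out = 0
    for i in range(len(ids)):
        cum_in += weights[i]
        if not in_set[i]:
            cum_out += 1
        es += cum_in / total_in - cum_out / n_out
    return es


def jasmine_oracle(counts, gene_ids, set_genes):
    """Explicit per-cell rank table and 2x2 enrichment table composite."""
    counts = np.asarray(counts, dtype=float)
    n_genes, n_cells = counts.shape
    ids = list(gene_ids)
    in_set = [g in set_genes for g in ids]
    set_size = sum(in_set)
    rank_comp, or_comp = [], []
    for j in range(n_cells):
        col = counts[:, j]
        expressed = [i for i in range(n_genes) if col[i] > 0]
        ranks = _avg_ranks([col[i] for i in expressed])
        set_ranks = [ranks[k] for k, i in enumerate(expressed) if in_set[i]]
        if expressed and set_ranks:
            rank_comp.append(sum(set_ranks) / len(set_ranks) / len(expressed))
        else:
            rank_comp.append(0.0)
        a = sum(1 for i in expressed if in_set[i])
        b = set_size - a
        c = len(expressed) - a
        d = (n_genes - set_size) - c
        if min(a, b, c, d) == 0:
            a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        or_comp.append(a * d / (b * c))

    def scale(v):
        lo, hi = min(v), max(v)
        if hi == lo:
            return [0.0] * len(v)
        return [(u - lo) / (hi - lo) for u in v]

    return [
        0.5 * (r + o) for r, o in zip(scale(rank_comp), scale(or_comp))
    ]


def aucell_oracle(column, gene_ids, set_genes, top_fraction):
    """Rank-by-rank recovery-curve enumeration for one sample."""
    vals = list(map(float, column))
    ids = list(gene_ids)
    order = sorted(range(len(ids)), key=lambda i: (-vals[i], ids[i]))
    m = math.ceil(top_fraction * len(ids))
    s = min(len([g for g in ids if g in set_genes]), m)
    area = 0
    recovered = 0
    for pos in range(m):
        if ids[order[pos]] in set_genes:
            recovered += 1
        area += recovered
    max_area = s * (s + 1) // 2 + s * (m - s)
    return area / max_area


def fisher_oracle(table):
    """Two-sided Fisher p by full hypergeometric enumeration (exact rationals).

    All tables with the observed margins share the denominator
    C(n, c1), so table probabilities are compared as exact integers.
    """
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    obs_num = math.comb(r1, a) * math.comb(r2, c1 - a)
    total = 0
    for aa in range(max(0, c1 - r2), min(r1, c1) + 1):
        num = math.comb(r1, aa) * math.comb(r2, c1 - aa)
        if num <= obs_num:
            total += num
    return float(Fraction(total, math.comb(n, c1)))


def wilcoxon_exact_oracle(x, y):
    """Exact two-sided rank-sum p by enumeration of all group assignments.

    Assumes no ties.  p = min(1, 2 * min(P(U <= u), P(U >= u))) over the
    permutation distribution of the Mann-Whitney U of the first group.
    """
    x, y = list(x), list(y)
    combined = sorted(x + y)
    assert len(set(combined)) == len(combined), "oracle requires no ties"
    nx = len(x)
    rank_of = {v: i + 1 for i, v in enumerate(combined)}
    u_obs = sum(rank_of[v] for v in x) - nx * (nx + 1) / 2
    us = [
        sum(subset) - nx * (nx + 1) / 2
        for subset in itertools.combinations(range(1, len(combined) + 1), nx)
    ]
    n_total = len(us)
    p_le = sum(1 for u in us if u <= u_obs) / n_total
    p_ge = sum(1 for u in us if u >= u_obs) / n_total
    return min(1.0, 2 * min(p_le, p_ge))


def hodges_lehmann_oracle(x, y):
    """Median of all pairwise differences x_i - y_j, by explicit listing."""
    diffs = sorted(xi - yj for xi in x for yj in y)
    k = len(diffs)
    mid = k // 2
    return diffs[mid] if k % 2 else 0.5 * (diffs[mid - 1] + diffs[mid])


def spearman_oracle(u, v):
    """Pearson correlation of explicitly constructed average ranks."""
    ru = np.array(_avg_ranks(list(u)))
    rv = np.array(_avg_ranks(list(v)))
    ru = ru - ru.mean()
    rv = rv - rv.mean()
    return float((ru * rv).sum() / np.sqrt((ru**2).sum() * (rv**2).sum()))


def welch_oracle(x, y):
    """Textbook Welch statistic, Satterthwaite df, and t-distribution p."""
    from scipy.stats import t as t_dist

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = len(x), len(y)
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    se2 = vx / nx + vy / ny
    t = (x.mean() - y.mean()) / math.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = 2 * t_dist.sf(abs(t), df)
    return t, df, p
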