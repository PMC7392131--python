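"""Independent brute-force oracles for the test suite.

Deliberately written without touching the package's own algorithms:
cell-level proportional fitting with explicit row/column loops, nested
counting for cross-tabs, rank statistics from first principles, and an
exhaustive permutation enumerator for the group tests.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def ipf_cells(seed_table, row_targets, col_targets, tol=1e-12, max_iter=10_000):
    """Classical cell-level IPF on a 2-D seed table (explicit loops)."""
    t = [list(map(float, row)) for row in seed_table]
    nr, nc = len(t), len(t[0])
    for _ in range(max_iter):
        for i in range(nr):
            s = sum(t[i])
            if s > 0:
                f = row_targets[i] / s
                for j in range(nc):
                    t[i][j] *= f
        for j in range(nc):
            s = sum(t[i][j] for i in range(nr))
            if s > 0:
                f = col_targets[j] / s
                for i in range(nr):
                    t[i][j] *= f
        worst = max(abs(sum(t[i]) - row_targets[i]) / row_targets[i] for i in range(nr))
        if worst < tol:
            break
    return np.array(t)


def crosstab_loops(rows, var_values, weights=None):
    """Cross-tabulation by a plain nested counting loop."""
    out: dict = {}
    if weights is None:
        weights = [1.0] * len(rows)
    for r, w in zip(rows, weights):
        key = tuple(var_values[v][r] for v in var_values)
        out[key] = out.get(key, 0.0) + w
    return out


def quantile_cumcount(values, q):
    """Smallest value whose cumulative count fraction reaches q."""
    vs = sorted(values)
    n = len(vs)
    for i, v in enumerate(vs, start=1):
        if i / n >= q:
            return v
    return vs[-1]


def weighted_quantile_cumweight(values, weights, q):
    """Smallest value whose cumulative normalized weight reaches q."""
    pairs = sorted(zip(values, weights))
    total = sum(w for _, w in pairs)
    cum = 0.0
    for v, w in pairs:
        cum += w
        if cum / total >= q:
            return v
    return pairs[-1][0]


def ranks_average(values):
    """Average ranks computed from first principles."""
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def kruskal_h(values, labels):
    """Tie-corrected Kruskal-Wallis H from the textbook formula."""
    n = len(values)
    ranks = ranks_average(values)
    groups = sorted(set(labels))
    h = 0.0
    for g in groups:
        rsum = sum(r for r, l in zip(ranks, labels) if l == g)
        ng = sum(1 for l in labels if l == g)
        h += rsum * rsum / ng
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    counts: dict = {}
    for v in values:
        counts[v] = counts.get(v, 0) + 1
    tie = sum(c**3 - c for c in counts.values())
    denom = 1.0 - tie / (n**3 - n)
    return h / denom if denom > 0 else 0.0


def pearson_chi2(table):
    """Pearson chi-square statistic with explicit expected counts."""
    table = [list(map(float, row)) for row in table]
    total = sum(sum(row) for row in table)
    row_sums = [sum(row) for row in table]
    col_sums = [sum(row[j] for row in table) for j in range(len(table[0]))]
    stat = 0.0
    for i, row in enumerate(table):
        for j, obs in enumerate(row):
            exp = row_sums[i] * col_sums[j] / total
            stat += (obs - exp) ** 2 / exp
    return stat


def kw_permutation_distribution(values, group_sizes):
    """Exact H over every assignment of values to groups (n <= 8)."""
    n = len(values)
    assert n == sum(group_sizes) and n <= 8
    idx = list(range(n))
    stats = []
    for perm in set(itertools.permutations(_labels(group_sizes))):
        stats.append(kruskal_h(values, list(perm)))
    return stats


def _labels(group_sizes):
    out = []
    for g, size in enumerate(group_sizes):
        out.extend([g] * size)
    return tuple(out)


def two_group_anova_f(a, b):
    """Closed-form two-sample ANOVA F = squared pooled-variance t."""
    na, nb = len(a), len(b)
    ma, mb = sum(a) / na, sum(b) / nb
    ssa = sum((x - ma) ** 2 for x in a)
    ssb = sum((x - mb) ** 2 for x in b)
    sp2 = (ssa + ssb) / (na + nb - 2)
    t = (ma - mb) / math.sqrt(sp2 * (1 / na + 1 / nb))
    return t * t
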