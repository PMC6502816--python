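"""Independent brute-force reference implementations used by the test suite.

Everything here is written as plain loops over the definitions, deliberately
ignoring how the package computes the same quantities.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy import stats


def anova_f_oracle(groups: list[list[float]]) -> tuple[float, float]:
    """One-way fixed-effects F from explicit sums of squares."""
    k = len(groups)
    ns = [len(g) for g in groups]
    n_total = sum(ns)
    grand = sum(sum(g) for g in groups) / n_total
    ss_between = sum(n * (sum(g) / n - grand) ** 2 for g, n in zip(groups, ns))
    ss_within = sum(sum((x - sum(g) / n) ** 2 for x in g) for g, n in zip(groups, ns))
    df_b, df_w = k - 1, n_total - k
    if ss_within == 0 and ss_between == 0:
        return 0.0, 1.0
    f = (ss_between / df_b) / (ss_within / df_w)
    return f, float(stats.f.sf(f, df_b, df_w))


def pooled_t_oracle(a: list[float], b: list[float]) -> tuple[float, float]:
    """Equal-variance two-sample t from the hand formula."""
    na, nb = len(a), len(b)
    ma, mb = sum(a) / na, sum(b) / nb
    va = sum((x - ma) ** 2 for x in a) / (na - 1)
    vb = sum((x - mb) ** 2 for x in b) / (nb - 1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    t = (ma - mb) / math.sqrt(sp2 * (1 / na + 1 / nb))
    p = 2 * float(stats.t.sf(abs(t), na + nb - 2))
    return t, p


def paired_t_oracle(diffs: list[float]) -> tuple[float, float]:
    """Paired t on per-pair differences: mean / (sd / sqrt(n))."""
    n = len(diffs)
    mean = sum(diffs) / n
    sd = math.sqrt(sum((d - mean) ** 2 for d in diffs) / (n - 1))
    t = mean / (sd / math.sqrt(n))
    p = 2 * float(stats.t.sf(abs(t), n - 1))
    return t, p


def bh_oracle(pvals: list[float]) -> list[float]:
    """Benjamini-Hochberg by the textbook definition (O(m^2) loops):
    adj_i = min over j with p_j >= p_i of p_j * m / rank(p_j), capped at 1."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    rank = {}
    for r, i in enumerate(order, start=1):
        rank[i] = r
    adj = []
    for i in range(m):
        candidates = [
            pvals[j] * m / rank[j] for j in range(m) if pvals[j] >= pvals[i]
        ]
        adj.append(min(1.0, min(candidates)))
    return adj


def auc_oracle(scores: list[float], labels: list[int]) -> float:
    """AUC by exhaustive concordant-pair counting, ties as 1/2."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p, n in itertools.product(pos, neg):
        if p > n:
            total += 1.0
        elif p == n:
            total += 0.5
    return total / (len(pos) * len(neg))


def manhattan_oracle(a: list[float], b: list[float]) -> float:
    return sum(abs(x - y) for x, y in zip(a, b))


def tukey_p_oracle(groups: list[list[float]], i: int, j: int) -> float:
    """Tukey-Kramer p for groups i vs j via the studentized-range definition."""
    k = len(groups)
    n_total = sum(len(g) for g in groups)
    means = [sum(g) / len(g) for g in groups]
    ss_within = sum(
        sum((x - m) ** 2 for x in g) for g, m in zip(groups, means)
    )
    df = n_total - k
    mse = ss_within / df
    ni, nj = len(groups[i]), len(groups[j])
    se = math.sqrt(mse / 2 * (1 / ni + 1 / nj))
    q = abs(means[i] - means[j]) / se
    return float(stats.studentized_range.sf(q, k, df))


def ari_oracle(a: list[int], b: list[int]) -> float:
    """Adjusted Rand index from the pair-counting contingency definition."""
    n = len(a)
    labels_a, labels_b = sorted(set(a)), sorted(set(b))
    table = np.zeros((len(labels_a), len(labels_b)))
    for x, y in zip(a, b):
        table[labels_a.index(x), labels_b.index(y)] += 1

    def comb2(x):
        return x * (x - 1) / 2

    sum_ij = sum(comb2(v) for v in table.flat)
    sum_a = sum(comb2(v) for v in table.sum(axis=1))
    sum_b = sum(comb2(v) for v in table.sum(axis=0))
    expected = sum_a * sum_b / comb2(n)
    max_index = (sum_a + sum_b) / 2
    if max_index == expected:
        return 0.0
    return float((sum_ij - expected) / (max_index - expected))
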