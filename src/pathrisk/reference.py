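"""Literal, slow reference implementations used as independent oracles.

These functions transcribe the defining formulas directly — a quadruple
loop for the HHG statistic, a step-by-step kernel-CDF / rank-statistic /
random-walk pass for ssGSVA — with no shared code with the optimized
production paths they are checked against.  They are intended for tiny
problem sizes only.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

__all__ = [
    "hhg_statistic_bruteforce",
    "hhg_exhaustive_pvalue",
    "ssgsva_literal",
]


def hhg_statistic_bruteforce(x, y) -> float:
    """HHG sum statistic by direct enumeration of all (i, j, k) triples.

    For each ordered pair (i, j) the remaining points are cross-classified
    by |x_i - x_k| <= |x_i - x_j| and |y_i - y_k| <= |y_i - y_j|; the pair
    contributes the Pearson chi-square of that 2x2 table, i.e.
    (N-2) * (A12*A21 - A11*A22)^2 / (A1. * A2. * A.1 * A.2), taken as zero
    whenever a margin is empty.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    if n < 3:
        raise ValueError("HHG needs at least 3 observations")
    total = 0.0
    for i in range(n):
        for j in range(n):
            if j == i:
                continue
            dx_ij = abs(x[i] - x[j])
            dy_ij = abs(y[i] - y[j])
            a11 = a12 = a21 = a22 = 0
            for k in range(n):
                if k == i or k == j:
                    continue
                cx = abs(x[i] - x[k]) <= dx_ij
                cy = abs(y[i] - y[k]) <= dy_ij
                if cx and cy:
                    a11 += 1
                elif cx:
                    a12 += 1
                elif cy:
                    a21 += 1
                else:
                    a22 += 1
            r1, r2 = a11 + a12, a21 + a22
            c1, c2 = a11 + a21, a12 + a22
            if r1 > 0 and r2 > 0 and c1 > 0 and c2 > 0:
                total += (n - 2) * (a12 * a21 - a11 * a22) ** 2 / (r1 * r2 * c1 * c2)
    return total


def hhg_exhaustive_pvalue(x, y, statistic=hhg_statistic_bruteforce) -> float:
    """Exact permutation P value by full enumeration of all N! pairings.

    Extreme events are permuted statistics >= the observed one (ties count
    as extreme), matching the Monte-Carlo convention.  Feasible for N <= 7.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    t_obs = statistic(x, y)
    tol = 1e-9 * (1.0 + abs(t_obs))  # ties count as extreme; float guard
    n_extreme = 0
    n_total = 0
    for perm in itertools.permutations(range(n)):
        n_total += 1
        if statistic(x, y[list(perm)]) >= t_obs - tol:
            n_extreme += 1
    return n_extreme / n_total


def _gauss_cdf(z: float) -> float:
    return 0.5 * (1.0 + math.erf(z / math.sqrt(2.0)))


def ssgsva_literal(expr: np.ndarray, genes: list, gene_sets: dict) -> np.ndarray:
    """Step-by-step single-sample GSVA scores.

    expr: genes x individuals array; gene_sets: name -> member gene list.
    Steps, written out one by one:
      1. per gene, a Gaussian-kernel CDF across individuals, bandwidth
         sample SD / 4 (empirical mid-CDF when the gene has zero variance);
      2. per individual, genes ranked by these values (largest first) and
         converted to the symmetric statistic |rank - p/2| with weight
         exponent tau = 1;
      3. a walk down the ranking accumulating weighted hits (set members,
         normalized by the total member weight) minus uniform misses;
      4. score = largest positive deviation - largest negative deviation
         magnitude.
    Returns a pathways x individuals array in the iteration order of
    gene_sets.
    """
    expr = np.asarray(expr, float)
    p, n = expr.shape
    gene_index = {g: i for i, g in enumerate(genes)}

    # step 1: kernel CDF per gene
    kcdf = np.zeros((p, n))
    for g in range(p):
        row = expr[g]
        sd = row.std(ddof=1)
        if sd > 0:
            h = sd / 4.0
            for j in range(n):
                s = 0.0
                for k in range(n):
                    s += _gauss_cdf((row[j] - row[k]) / h)
                kcdf[g, j] = s / n
        else:
            for j in range(n):
                less = sum(1 for k in range(n) if row[k] < row[j])
                equal = sum(1 for k in range(n) if row[k] == row[j])
                kcdf[g, j] = (less + 0.5 * equal) / n
    scores = np.zeros((len(gene_sets), n))
    for si, (name, members) in enumerate(gene_sets.items()):
        member_rows = set(gene_index[m] for m in members if m in gene_index)
        for j in range(n):
            # step 2: rank genes, largest kcdf first (stable on gene order)
            order = sorted(range(p), key=lambda g: (-kcdf[g, j], g))
            rank_of = {g: r + 1 for r, g in enumerate(order)}
            weight = {g: abs(rank_of[g] - p / 2.0) for g in range(p)}
            w_in = sum(weight[g] for g in member_rows)
            n_out = p - len(member_rows)
            # steps 3-4: random walk over the ranking
            dev = 0.0
            max_pos = 0.0
            max_neg = 0.0
            for g in order:
                if g in member_rows:
                    dev += weight[g] / w_in
                else:
                    dev -= 1.0 / n_out
                max_pos = max(max_pos, dev)
                max_neg = min(max_neg, dev)
            scores[si, j] = max_pos - abs(max_neg)
    return scores
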