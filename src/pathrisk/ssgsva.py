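"""Single-sample gene set variation analysis (ssGSVA).

Per-individual pathway scores from rank-based enrichment of
kernel-CDF-transformed expression:

1. per gene, a Gaussian-kernel cumulative density across individuals
   (bandwidth = sample SD / 4; empirical mid-CDF for zero-variance genes);
2. per individual, genes are ranked by these values (largest first) and
   given the symmetric rank statistic ``|rank - p/2|`` (weight exponent
   tau = 1);
3. a walk down the ranking accumulates weighted hits (set members,
   normalized by total member weight) minus uniform misses;
4. the score is the maximum positive deviation minus the magnitude of the
   maximum negative deviation, hence bounded in [-1, 1].

Two size-filtering conventions are exposed: "strict" keeps pathways whose
expressed-gene count lies in [10, 300]; "broad" keeps every pathway with
at least 2 expressed genes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import ndtr
from scipy.stats import rankdata, ranksums

from .containers import GeneSetCollection, ScoreMatrix

FILTER_MODES = {"strict": (10, 300), "broad": (2, None)}


def filter_gene_sets(sets: GeneSetCollection, expr: ScoreMatrix,
                     mode: str = "strict") -> GeneSetCollection:
    """Keep pathways by expressed-member count (counted after intersecting
    each member list with the expression matrix's genes)."""
    if mode not in FILTER_MODES:
        raise ValueError(f"unknown mode {mode!r}; use one of {sorted(FILTER_MODES)}")
    lo, hi = FILTER_MODES[mode]
    expressed = set(expr.features)
    kept = {}
    for name, members in sets.items():
        n = len(set(members) & expressed)
        if n >= lo and (hi is None or n <= hi):
            kept[name] = members
    return GeneSetCollection(kept)


def kernel_cdf(expr_values: np.ndarray) -> np.ndarray:
    """Gaussian-kernel CDF of each entry within its gene (row).

    Bandwidth is the row's sample SD divided by 4; rows with zero variance
    fall back to the empirical mid-rank CDF.
    """
    x = np.asarray(expr_values, float)
    p, n = x.shape
    if n < 3:
        raise ValueError("kernel CDF needs at least 3 individuals")
    out = np.empty_like(x)
    sd = x.std(axis=1, ddof=1)
    for g in range(p):
        if sd[g] > 0:
            h = sd[g] / 4.0
            out[g] = ndtr((x[g][:, None] - x[g][None, :]) / h).mean(axis=1)
        else:
            out[g] = rankdata(x[g], method="average") / n - 0.5 / n
    return out


def ssgsva_scores(expr: ScoreMatrix, sets: GeneSetCollection) -> ScoreMatrix:
    """Pathway x individual enrichment scores for pre-filtered gene sets."""
    x = expr.to_array()
    p, n = x.shape
    genes = expr.features
    kcdf = kernel_cdf(x)
    # rank genes per individual, largest kernel-CDF first; stable sort
    # makes ties break on gene order, keeping scores deterministic
    order = np.argsort(-kcdf, axis=0, kind="stable")  # (p, n): gene ids by position
    ranks = np.empty_like(order)
    pos = np.arange(1, p + 1)[:, None] * np.ones((1, n), dtype=int)
    np.put_along_axis(ranks, order, pos, axis=0)
    weight = np.abs(ranks - p / 2.0)  # tau = 1
    gene_row = {g: i for i, g in enumerate(genes)}
    out = np.zeros((len(sets), n))
    n_used = {}
    for si, (name, members) in enumerate(sets.items()):
        rows = sorted({gene_row[m] for m in members if m in gene_row})
        m = len(rows)
        if m == 0:
            raise ValueError(f"gene set {name!r} has no expressed members; "
                             "filter gene sets first")
        n_used[name] = m
        member = np.zeros(p, bool)
        member[rows] = True
        member_sorted = member[order]                   # (p, n) walk order
        w_sorted = np.where(member_sorted, np.take_along_axis(weight, order, axis=0), 0.0)
        w_in = w_sorted.sum(axis=0)                     # per individual
        w_in[w_in == 0] = 1.0
        miss = 1.0 / (p - m) if p > m else 0.0
        steps = np.where(member_sorted, w_sorted / w_in, -miss)
        walk = np.cumsum(steps, axis=0)
        out[si] = np.maximum(walk.max(axis=0), 0) - np.abs(np.minimum(walk.min(axis=0), 0))
    values = pd.DataFrame(out, index=list(sets.names()), columns=expr.individuals)
    return ScoreMatrix(values, n_used=pd.Series(n_used), label=expr.label)


def group_score_comparison(scores: ScoreMatrix, groups) -> dict:
    """Two-sided Wilcoxon rank-sum test of per-individual mean pathway
    scores between two groups (e.g. PRS > 0 vs PRS < 0)."""
    groups = np.asarray(groups)
    means = scores.to_array().mean(axis=0)
    a = means[groups == 1]
    b = means[groups == 0]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be nonempty")
    stat, p = ranksums(a, b)
    return {"statistic": float(stat), "pvalue": float(p),
            "significant": bool(p < 0.05),
            "n_high": int(len(a)), "n_low": int(len(b))}


def high_ratio_fraction(sets: GeneSetCollection, expr: ScoreMatrix) -> float:
    """Fraction of pathways in which strictly more than half of the member
    genes are quantified by the expression matrix."""
    if len(sets) == 0:
        raise ValueError("empty gene set collection")
    expressed = set(expr.features)
    n_high = 0
    for _, members in sets.items():
        uniq = set(members)
        if len(uniq & expressed) / len(uniq) > 0.5:
            n_high += 1
    return n_high / len(sets)


def duplicate_score_groups(scores: ScoreMatrix) -> dict:
    """Group pathways whose score vectors are bitwise identical.

    Returns {first-seen name: [all members]} for groups of size >= 2; the
    mechanism by which membership-identical intersections collapse to the
    same score, which the SEM stage must deduplicate.
    """
    seen: dict[bytes, list[str]] = {}
    for name in scores.features:
        key = scores.values.loc[name].to_numpy(float).tobytes()
        seen.setdefault(key, []).append(name)
    return {names[0]: names for names in seen.values() if len(names) > 1}
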