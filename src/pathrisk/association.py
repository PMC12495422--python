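"""Pathway–risk dependence testing.

For each pathway the winsorized per-individual scores are tested against
the winsorized risk score with the HHG distance-based statistic, whose
empirical P value comes from an adaptive permutation scheme: at least
``min_perms`` permutations of the pairing, then early stop once at least
``stop_extreme`` permuted statistics have reached the observed one, up to
``max_perms``.  Region-level significance uses Storey q-values: the
empirical P whose q-value is closest to the FDR target is selected, and
each pathway's critical value is the n-th most extreme of its own permuted
statistics with n = ceil(selected P x its permutation count).

Normality of the scores (Shapiro–Wilk) is reported only as the motivation
for a distribution-free dependence statistic; the pipeline always proceeds
with HHG.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

from ._hhg import hhg_perm_stats, hhg_statistic_fast

logger = logging.getLogger("pathrisk")

__all__ = [
    "winsorize", "shapiro_wilk", "hhg_statistic", "adaptive_permutation",
    "storey_qvalues", "call_significance", "consistency_check",
    "AssociationRecord", "RegionThreshold", "region_association",
]


def winsorize(scores, trim: float = 0.2) -> np.ndarray:
    """Clamp values outside the [trim, 1-trim] quantiles to those quantiles
    (type-7 / linear-interpolation quantiles, the R default)."""
    if not 0 <= trim < 0.5:
        raise ValueError("trim must be in [0, 0.5)")
    x = np.asarray(scores, float)
    if trim == 0:
        return x.copy()
    lo, hi = np.quantile(x, [trim, 1 - trim])
    return np.clip(x, lo, hi)


def shapiro_wilk(scores) -> tuple[float, float]:
    """Shapiro–Wilk W and P for a non-constant sample of size 3..5000."""
    x = np.asarray(scores, float)
    if not 3 <= len(x) <= 5000:
        raise ValueError("Shapiro-Wilk needs 3 <= n <= 5000")
    if np.ptp(x) == 0:
        raise ValueError("constant sample")
    w, p = scipy.stats.shapiro(x)
    return float(w), float(p)


def hhg_statistic(x, y) -> float:
    """HHG sum statistic with absolute-difference distances (univariate)."""
    return hhg_statistic_fast(np.asarray(x, float), np.asarray(y, float))


def _spearman_abs(x, y) -> float:
    return abs(float(scipy.stats.spearmanr(x, y).statistic))


def _spearman_abs_batch(x, y, perms) -> np.ndarray:
    rx = scipy.stats.rankdata(x)
    ry = scipy.stats.rankdata(y)
    rx = (rx - rx.mean()) / rx.std()
    ry = (ry - ry.mean()) / ry.std()
    return np.abs(ry[perms] @ rx) / len(x)


@dataclass
class AssociationRecord:
    pathway: str
    hhg_T: float
    n_perms: int
    n_extreme: int
    empirical_p: float
    perm_stats: np.ndarray = field(repr=False)
    q_value: float = np.nan
    threshold_stat: float = np.nan
    significant: bool = False

    def __post_init__(self):
        assert len(self.perm_stats) == self.n_perms
        assert abs(self.empirical_p - self.n_extreme / self.n_perms) < 1e-12


def adaptive_permutation(x, y, min_perms: int = 1000, max_perms: int = 10000,
                         stop_extreme: int = 15, seed=None, rng=None,
                         batch: int = 250, statistic: str = "hhg",
                         plus_one: bool = False,
                         pathway: str = "") -> AssociationRecord:
    """Empirical P for dependence of ``y`` on ``x`` by adaptive permutation.

    An extreme event is a permuted statistic >= the observed one (ties
    count as extreme).  Permutations run in batches; the stop rule
    (n_extreme >= stop_extreme, after at least ``min_perms``) is checked at
    batch boundaries.  ``plus_one`` switches the plain ratio k/B to
    (k+1)/(B+1) for users wanting a strictly positive P; the stored
    ``empirical_p`` follows the chosen convention.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d and of equal length")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if min_perms > max_perms:
        raise ValueError("min_perms > max_perms")
    if statistic == "hhg":
        stat, stat_batch = hhg_statistic, hhg_perm_stats
    elif statistic == "spearman":
        stat, stat_batch = _spearman_abs, _spearman_abs_batch
    else:
        raise ValueError(f"unknown statistic {statistic!r}")
    if rng is None:
        rng = np.random.default_rng(seed)
    t_obs = stat(x, y)
    tol = _tie_tol(t_obs)
    n = len(x)
    all_stats: list[np.ndarray] = []
    n_done = 0
    n_extreme = 0
    while n_done < max_perms:
        b = min(batch, max_perms - n_done)
        perms = rng.permuted(np.tile(np.arange(n), (b, 1)), axis=1)
        ts = stat_batch(x, y, perms)
        all_stats.append(ts)
        n_extreme += int((ts >= t_obs - tol).sum())
        n_done += b
        if n_done >= min_perms and n_extreme >= stop_extreme:
            break
    perm_stats = np.sort(np.concatenate(all_stats))
    if plus_one:
        emp_p = (n_extreme + 1) / (n_done + 1)
    else:
        emp_p = n_extreme / n_done
    rec = AssociationRecord(pathway=pathway, hhg_T=t_obs, n_perms=n_done,
                            n_extreme=n_extreme, empirical_p=n_extreme / n_done,
                            perm_stats=perm_stats)
    rec.empirical_p = emp_p
    return rec


def storey_qvalues(p, lam: float = 0.5, pi0: float | None = None) -> np.ndarray:
    """Storey q-values with a single-lambda pi0 estimate.

    pi0 = #{p > lambda} / (m (1 - lambda)), capped at 1; q_i is the
    descending cumulative minimum of pi0 * m * p_(i) / i mapped back to the
    input order.  With ``pi0`` forced to 1 this reduces to
    Benjamini–Hochberg.
    """
    p = np.asarray(p, float)
    if p.size == 0:
        raise ValueError("empty P vector")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("P values must lie in [0, 1]")
    m = p.size
    if pi0 is None:
        pi0 = min(1.0, (p > lam).sum() / (m * (1.0 - lam)))
    order = np.argsort(p, kind="mergesort")
    vals = pi0 * m * p[order] / np.arange(1, m + 1)
    q_sorted = np.minimum(np.minimum.accumulate(vals[::-1])[::-1], 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def _tie_tol(t_obs: float) -> float:
    # permuted statistics mathematically equal to the observed one must
    # count as extreme; a relative tolerance guards float rounding
    return 1e-9 * (1.0 + abs(t_obs))


def exhaustive_permutation_pvalue(x, y, statistic: str = "hhg") -> float:
    """Exact permutation P by enumerating every pairing (feasible N <= 8).

    Extreme events are permuted statistics >= the observed one, the same
    convention as the Monte-Carlo procedure.
    """
    import itertools

    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    if n > 8:
        raise ValueError("full enumeration is limited to N <= 8")
    stat = hhg_statistic if statistic == "hhg" else _spearman_abs
    t_obs = stat(x, y)
    tol = _tie_tol(t_obs)
    n_extreme = 0
    n_total = 0
    for perm in itertools.permutations(range(n)):
        n_total += 1
        if stat(x, y[list(perm)]) >= t_obs - tol:
            n_extreme += 1
    return n_extreme / n_total


@dataclass
class RegionThreshold:
    region: str
    selected_empirical_p: float
    q_at_selection: float


def call_significance(records: list, region: str = "",
                      q_target: float = 0.05,
                      lam: float = 0.5) -> tuple[list, RegionThreshold]:
    """Per-pathway significance via the region-level Storey threshold rule.

    Steps: (1) q-values over the region's empirical P values; (2) select
    the empirical P whose q is closest to ``q_target`` (ties break to the
    smaller P); (3) per pathway, n = ceil(selected P x its n_perms),
    clamped to [1, n_perms], and the critical value is its n-th most
    extreme permuted statistic; a pathway is significant iff its observed
    statistic strictly exceeds that critical value.
    """
    if not records:
        raise ValueError("no records")
    p = np.array([r.empirical_p for r in records])
    q = storey_qvalues(p, lam=lam)
    for r, qi in zip(records, q):
        r.q_value = float(qi)
    dist = np.abs(q - q_target)
    best = dist.min()
    cand = np.where(dist == best)[0]
    sel = cand[np.argmin(p[cand])]
    sel_p = float(p[sel])
    thr = RegionThreshold(region=region, selected_empirical_p=sel_p,
                          q_at_selection=float(q[sel]))
    for r in records:
        n = math.ceil(sel_p * r.n_perms)
        if n > r.n_perms:
            logger.warning("threshold index %d exceeds n_perms for %s; clamped",
                           n, r.pathway)
            n = r.n_perms
        n = max(n, 1)
        # n-th smallest permuted "P value" == n-th largest permuted statistic
        r.threshold_stat = float(r.perm_stats[r.n_perms - n])
        r.significant = bool(r.hhg_T > r.threshold_stat)
    return records, thr


def consistency_check(records: list, p_cut: float = 0.001) -> dict:
    """Agreement between the plain empirical-P call (P < p_cut) and the
    Storey-threshold call."""
    by_p = {r.pathway for r in records if r.empirical_p < p_cut}
    by_thr = {r.pathway for r in records if r.significant}
    union = by_p | by_thr
    jaccard = len(by_p & by_thr) / len(union) if union else 1.0
    return {"n_by_p": len(by_p), "n_by_threshold": len(by_thr),
            "n_both": len(by_p & by_thr), "jaccard": jaccard,
            "matched": by_p == by_thr}


def region_association(prs_scores, pathway_scores, region: str = "",
                       trim: float = 0.2, winsorize_prs: bool = True,
                       winsorize_scores: bool = True,
                       min_perms: int = 1000, max_perms: int = 10000,
                       stop_extreme: int = 15, seed: int = 0,
                       statistic: str = "hhg",
                       q_target: float = 0.05) -> pd.DataFrame:
    """Run the full association stage for one region.

    ``prs_scores``: per-individual risk scores (pandas Series or array
    aligned with the score matrix columns); ``pathway_scores``: a
    ScoreMatrix.  Per-pathway permutation streams are spawned from ``seed``
    so results do not depend on pathway order or on each other.
    """
    from .containers import ScoreMatrix

    if isinstance(pathway_scores, ScoreMatrix):
        names = pathway_scores.features
        mat = pathway_scores.to_array()
        if hasattr(prs_scores, "reindex"):
            prs_scores = prs_scores.reindex(pathway_scores.individuals)
    else:
        mat = np.asarray(pathway_scores, float)
        names = [f"pathway{i}" for i in range(mat.shape[0])]
    x = np.asarray(prs_scores, float)
    if winsorize_prs:
        x = winsorize(x, trim)
    root = np.random.SeedSequence(seed)
    children = root.spawn(len(names))
    records = []
    for row, name, ss in zip(mat, names, children):
        y = winsorize(row, trim) if winsorize_scores else row.copy()
        rec = adaptive_permutation(
            x, y, min_perms=min_perms, max_perms=max_perms,
            stop_extreme=stop_extreme, rng=np.random.default_rng(ss),
            statistic=statistic, pathway=name)
        records.append(rec)
    records, thr = call_significance(records, region=region, q_target=q_target)
    out = pd.DataFrame(
        {"pathway": [r.pathway for r in records],
         "T": [r.hhg_T for r in records],
         "n_perms": [r.n_perms for r in records],
         "empirical_p": [r.empirical_p for r in records],
         "q": [r.q_value for r in records],
         "threshold": [r.threshold_stat for r in records],
         "significant": [r.significant for r in records]}).set_index("pathway")
    out.attrs["region_threshold"] = thr
    out.attrs["records"] = records
    return out
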