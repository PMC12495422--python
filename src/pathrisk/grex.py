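"""Genetically regulated expression (GReX) from eQTL weight models.

Predicted expression of a gene is the weighted sum of effect-allele
dosages over the gene's model variants.  Alleles are harmonized between
the weight table and the genotype records (direct match, REF/ALT swap, or
strand complement); entries that cannot be harmonized, or whose variant is
absent after QC, are skipped and counted, and a gene with no usable
entries is dropped rather than NaN-filled.  Missing dosages are
mean-imputed per variant before scoring.  No intercept or normalization is
applied: downstream pathway scoring is rank-based, so location and scale
are immaterial.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .containers import DosageMatrix, ScoreMatrix
from .genotype import _COMPLEMENT

logger = logging.getLogger("pathrisk")


def _orient(effect, noneffect, ref, alt):
    """How a model entry's effect allele maps onto the VCF ALT dosage.

    Returns +1 (effect allele is ALT), -1 (effect allele is REF, so the
    effect dosage is 2 - ALT dosage), or 0 (not harmonizable).
    """
    if effect == alt and noneffect == ref:
        return 1
    if effect == ref and noneffect == alt:
        return -1
    ce, cn = _COMPLEMENT.get(effect), _COMPLEMENT.get(noneffect)
    if ce == alt and cn == ref:
        return 1
    if ce == ref and cn == alt:
        return -1
    return 0


def predict_expression(geno: DosageMatrix, weights: pd.DataFrame,
                       tissue: str | None = None) -> ScoreMatrix:
    """Predict per-individual expression for every gene in the weight table.

    ``weights`` columns: gene, variant, effect_allele, noneffect_allele,
    weight (and optionally tissue, filtered when ``tissue`` is given).
    """
    if tissue is not None and "tissue" in weights.columns:
        weights = weights[weights["tissue"] == tissue]
    var_index = {vid: j for j, vid in enumerate(geno.variants["id"])}
    ref = geno.variants["ref"].to_numpy()
    alt = geno.variants["alt"].to_numpy()
    dos = geno.imputed_dosages()
    n_ind = geno.n_individuals
    expr: dict[str, np.ndarray] = {}
    n_used: dict[str, int] = {}
    n_skipped_absent = 0
    n_skipped_mismatch = 0
    for gene, grp in weights.groupby("gene", sort=True):
        acc = np.zeros(n_ind)
        used = 0
        for entry in grp.itertuples(index=False):
            j = var_index.get(entry.variant)
            if j is None:
                n_skipped_absent += 1
                continue
            sign = _orient(entry.effect_allele, entry.noneffect_allele,
                           ref[j], alt[j])
            if sign == 0:
                n_skipped_mismatch += 1
                continue
            eff_dos = dos[:, j] if sign > 0 else 2.0 - dos[:, j]
            acc = acc + entry.weight * eff_dos
            used += 1
        if used > 0:
            expr[gene] = acc
            n_used[gene] = used
    if n_skipped_absent or n_skipped_mismatch:
        logger.warning("predict_expression: skipped %d absent and %d "
                       "unharmonizable model entries",
                       n_skipped_absent, n_skipped_mismatch)
    values = pd.DataFrame(expr, index=geno.individuals).T
    out = ScoreMatrix(values, n_used=pd.Series(n_used), label=tissue or "")
    out.n_skipped_absent = n_skipped_absent
    out.n_skipped_mismatch = n_skipped_mismatch
    return out


def region_correlation(expr_by_region: dict) -> pd.DataFrame:
    """Pearson correlation between regions' per-gene average expression.

    For each region the expression of every gene is averaged across
    individuals; each pair of regions is correlated over the intersection
    of their gene lists (NaN when fewer than 3 genes are shared).
    """
    if len(expr_by_region) < 2:
        raise ValueError("need at least 2 regions")
    means = {r: e.values.mean(axis=1) for r, e in expr_by_region.items()}
    regions = list(means)
    out = pd.DataFrame(np.eye(len(regions)), index=regions, columns=regions)
    for a in range(len(regions)):
        for b in range(a + 1, len(regions)):
            ma, mb = means[regions[a]], means[regions[b]]
            common = ma.index.intersection(mb.index)
            if len(common) < 3:
                r = np.nan
            else:
                r = float(np.corrcoef(ma[common], mb[common])[0, 1])
            out.iloc[a, b] = out.iloc[b, a] = r
    return out
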