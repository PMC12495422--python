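"""Polygenic risk scoring from harmonized GWAS summary statistics.

The pipeline consumes per-variant effect sizes as given (posterior or
marginal — LD-aware shrinkage is upstream of this package); its job is
allele harmonization against the genotype records and the dosage-weighted
sum, by default on the average-per-allele convention (sum / (2 * M) with M
the number of variants used), with a raw-sum toggle.  Only rank order
matters downstream, so the convention is cosmetic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .containers import DosageMatrix
from .genotype import AMBIGUOUS_PAIRS, _COMPLEMENT

logger = logging.getLogger("pathrisk")


def harmonize(stats: pd.DataFrame, geno: DosageMatrix) -> pd.DataFrame:
    """Align summary-statistic effect alleles to the genotype ALT alleles.

    Variants are matched by id.  A1/A2 equal to alt/ref keeps the effect
    size; ref/alt flips its sign; strand-complement matches are
    complemented first and then follow the same rule.  Strand-ambiguous
    (A/T, C/G) and unmatched variants are dropped; counts of every action
    are stored in ``result.attrs["harmonization"]``.
    """
    counts = {"kept": 0, "sign_flipped": 0, "strand_complemented": 0,
              "ambiguous_dropped": 0, "unmatched_dropped": 0,
              "mismatch_dropped": 0}
    vmeta = geno.variants.set_index("id")
    rows = []
    for rec in stats.itertuples(index=False):
        a1, a2 = rec.a1, rec.a2
        if (a1, a2) in AMBIGUOUS_PAIRS:
            counts["ambiguous_dropped"] += 1
            continue
        if rec.variant not in vmeta.index:
            counts["unmatched_dropped"] += 1
            continue
        ref, alt = vmeta.at[rec.variant, "ref"], vmeta.at[rec.variant, "alt"]
        beta = rec.beta
        if a1 == alt and a2 == ref:
            counts["kept"] += 1
        elif a1 == ref and a2 == alt:
            beta = -beta
            counts["sign_flipped"] += 1
        else:
            c1, c2 = _COMPLEMENT.get(a1), _COMPLEMENT.get(a2)
            if c1 == alt and c2 == ref:
                counts["strand_complemented"] += 1
            elif c1 == ref and c2 == alt:
                beta = -beta
                counts["strand_complemented"] += 1
                counts["sign_flipped"] += 1
            else:
                counts["mismatch_dropped"] += 1
                continue
        rows.append({"variant": rec.variant, "a1": alt, "a2": ref,
                     "beta": beta, "se": rec.se, "p": rec.p})
    out = pd.DataFrame(rows, columns=["variant", "a1", "a2", "beta", "se", "p"])
    out.attrs["harmonization"] = counts
    logger.info("harmonize: %s", counts)
    return out


@dataclass
class PrsVector:
    scores: pd.Series            # index: individual id
    n_variants_used: int
    average: bool

    def __post_init__(self):
        if self.scores.isna().any():
            raise ValueError("PRS has missing individuals")


def score_prs(geno: DosageMatrix, stats: pd.DataFrame,
              average: bool = True) -> PrsVector:
    """score(i) = sum_j beta_j * dosage_ij, divided by 2M when ``average``.

    ``stats`` must already be harmonized (effect allele = ALT).  Missing
    dosages are mean-imputed per variant.
    """
    var_index = {vid: j for j, vid in enumerate(geno.variants["id"])}
    cols, betas = [], []
    for rec in stats.itertuples(index=False):
        j = var_index.get(rec.variant)
        if j is not None:
            cols.append(j)
            betas.append(rec.beta)
    m = len(cols)
    if m == 0:
        raise ValueError("no summary variants present in the genotype matrix")
    dos = geno.imputed_dosages()[:, cols]
    raw = dos @ np.asarray(betas)
    if average:
        raw = raw / (2.0 * m)
    return PrsVector(pd.Series(raw, index=geno.individuals), m, average)


def phenotype_correlation(prs: PrsVector, pheno: pd.DataFrame) -> pd.DataFrame:
    """Ties-corrected Spearman rho and P between the risk score and each
    phenotype column (binary group, ordinal Braak-like / Thal-like stage)."""
    common = prs.scores.index.intersection(pheno.index)
    if len(common) < 3:
        raise ValueError("need at least 3 overlapping individuals")
    s = prs.scores[common]
    rows = []
    for col in pheno.columns:
        y = pheno.loc[common, col].to_numpy(float)
        if np.all(y == y[0]):
            rows.append({"phenotype": col, "rho": np.nan, "pvalue": np.nan,
                         "undefined": True})
            continue
        rho, p = spearmanr(s.to_numpy(), y)
        rows.append({"phenotype": col, "rho": float(rho), "pvalue": float(p),
                     "undefined": False})
    return pd.DataFrame(rows).set_index("phenotype")
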