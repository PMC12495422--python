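"""Genotype input, PRS-guideline quality control and structure checking.

QC follows the conventional pre-PRS filter battery (call-rate filters on
variants and individuals, minor-allele frequency, Hardy–Weinberg exact
test, strand-ambiguous and duplicated variants).  Population structure is
assessed by PCA of standardized dosages with a Tracy–Widom test on the
leading eigenvalue, using moment ("effective marker") normalization and a
small embedded table of TW1 quantiles.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import DosageMatrix

logger = logging.getLogger("pathrisk")

AMBIGUOUS_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class VcfParseError(ValueError):
    pass


def read_vcf(path) -> DosageMatrix:
    """Load biallelic SNP records from a VCF into a dosage matrix.

    Dosage is the ALT-allele count; multiallelic and non-SNP records are
    skipped (with a logged count); missing genotypes are masked.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path), gts012=True)
    except Exception as exc:  # pragma: no cover - htslib-level failure
        raise VcfParseError(f"cannot open VCF {path}: {exc}") from exc
    individuals = list(vcf.samples)
    ids, chroms, poss, refs, alts = [], [], [], [], []
    dosage_rows, missing_rows = [], []
    n_skipped = 0
    for ln, var in enumerate(vcf, start=1):
        try:
            if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
                n_skipped += 1
                continue
            gts = var.gt_types  # 0=hom ref, 1=het, 2=hom alt, 3=missing
            miss = gts == 3
            dos = gts.astype(np.float64)
            dos[miss] = 0.0
            vid = var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}"
            ids.append(vid)
            chroms.append(var.CHROM)
            poss.append(var.POS)
            refs.append(var.REF)
            alts.append(var.ALT[0])
            dosage_rows.append(dos)
            missing_rows.append(miss)
        except Exception as exc:
            raise VcfParseError(f"malformed VCF record #{ln} in {path}: {exc}") from exc
    if n_skipped:
        logger.info("read_vcf: skipped %d multiallelic/non-SNP records", n_skipped)
    if not ids:
        raise VcfParseError(f"no biallelic SNP records in {path}")
    variants = pd.DataFrame(
        {"id": ids, "chrom": chroms, "pos": poss, "ref": refs, "alt": alts})
    geno = DosageMatrix(individuals, variants,
                        np.array(dosage_rows).T, np.array(missing_rows).T)
    geno.n_skipped_records = n_skipped
    return geno


def hwe_exact_midp(n_het: int, n_hom_ref: int, n_hom_alt: int) -> float:
    """Mid-P Hardy–Weinberg exact test on genotype counts.

    Enumerates the conditional distribution of the heterozygote count given
    the allele counts and returns the mid-P value (half weight on tables
    exactly as probable as the observed one).
    """
    n = n_het + n_hom_ref + n_hom_alt
    if n == 0:
        return 1.0
    n_rare = 2 * min(n_hom_ref, n_hom_alt) + n_het
    if n_rare == 0:
        return 1.0
    # heterozygote counts share the parity of the rare-allele count
    h_mid = n_rare * (2 * n - n_rare) / (2.0 * n - 1.0)
    h_start = int(h_mid)
    if (h_start % 2) != (n_rare % 2):
        h_start += 1
    if h_start > n_rare:
        h_start -= 2
    if h_start < 0:
        h_start += 2
    probs = {h_start: 1.0}
    h = h_start
    while h >= 2:  # downward recurrence
        probs[h - 2] = probs[h] * h * (h - 1.0) / (
            (n_rare - h + 2.0) * (2 * n - n_rare - h + 2.0))
        h -= 2
    h = h_start
    while h + 2 <= n_rare:
        probs[h + 2] = probs[h] * (n_rare - h) * (2 * n - n_rare - h) / (
            (h + 2.0) * (h + 1.0))
        h += 2
    total = sum(probs.values())
    p_obs = probs.get(n_het, 0.0) / total
    p = sum(v / total for v in probs.values() if v / total <= p_obs * (1 + 1e-12))
    return min(1.0, p - 0.5 * p_obs)


@dataclass
class QcReport:
    n_variants_in: int
    n_individuals_in: int
    n_variants_out: int = 0
    n_individuals_out: int = 0
    removed: dict = field(default_factory=dict)
    thresholds: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [("variants_in", self.n_variants_in),
                ("individuals_in", self.n_individuals_in)]
        rows += [(f"removed_{k}", v) for k, v in self.removed.items()]
        rows += [("variants_out", self.n_variants_out),
                 ("individuals_out", self.n_individuals_out)]
        return pd.DataFrame(rows, columns=["item", "count"])


def qc_genotypes(geno: DosageMatrix, t_geno: float = 0.01, t_mind: float = 0.01,
                 t_maf: float = 0.01, t_hwe: float = 1e-6
                 ) -> tuple[DosageMatrix, QcReport]:
    """Apply the standard pre-PRS genotype filters, in order.

    1. variants with missingness > ``t_geno``;
    2. individuals with missingness > ``t_mind``;
    3. variants with minor-allele frequency < ``t_maf``;
    4. variants failing the HWE mid-P exact test at ``t_hwe``;
    5. strand-ambiguous (A/T, C/G) variants;
    6. duplicated variant ids (all copies past the first).
    """
    if geno.n_variants == 0 or geno.n_individuals == 0:
        raise ValueError("empty dosage matrix")
    report = QcReport(geno.n_variants, geno.n_individuals,
                      thresholds={"t_geno": t_geno, "t_mind": t_mind,
                                  "t_maf": t_maf, "t_hwe": t_hwe})
    var_miss = geno.missing.mean(axis=0)
    keep_v = var_miss <= t_geno
    report.removed["variant_missingness"] = int((~keep_v).sum())
    geno = geno.select_variants(keep_v)

    ind_miss = geno.missing.mean(axis=1) if geno.n_variants else np.zeros(geno.n_individuals)
    keep_i = ind_miss <= t_mind
    report.removed["individual_missingness"] = int((~keep_i).sum())
    geno = geno.select_individuals(keep_i)
    if geno.n_individuals == 0:
        raise ValueError("all individuals removed by QC")

    af = geno.allele_freq()
    maf = np.minimum(af, 1 - af)
    keep_v = maf >= t_maf
    report.removed["maf"] = int((~keep_v).sum())
    geno = geno.select_variants(keep_v)

    hwe_p = np.ones(geno.n_variants)
    rounded = np.rint(geno.dosages)
    for v in range(geno.n_variants):
        ok = ~geno.missing[:, v]
        d = rounded[ok, v]
        hwe_p[v] = hwe_exact_midp(int((d == 1).sum()), int((d == 0).sum()),
                                  int((d == 2).sum()))
    keep_v = hwe_p >= t_hwe
    report.removed["hwe"] = int((~keep_v).sum())
    geno = geno.select_variants(keep_v)

    pairs = list(zip(geno.variants["ref"], geno.variants["alt"]))
    keep_v = np.array([p not in AMBIGUOUS_PAIRS for p in pairs])
    report.removed["strand_ambiguous"] = int((~keep_v).sum())
    geno = geno.select_variants(keep_v)

    keep_v = ~geno.variants["id"].duplicated().to_numpy()
    report.removed["duplicate_id"] = int((~keep_v).sum())
    geno = geno.select_variants(keep_v)

    if geno.n_variants == 0:
        raise ValueError("empty after QC: all variants removed")
    report.n_variants_out = geno.n_variants
    report.n_individuals_out = geno.n_individuals
    logger.info("QC: %d -> %d variants, %d -> %d individuals",
                report.n_variants_in, report.n_variants_out,
                report.n_individuals_in, report.n_individuals_out)
    return geno, report


# Approximate upper-tail quantiles of the Tracy-Widom TW1 distribution
# (Gaussian orthogonal ensemble).  (statistic value, upper-tail probability).
_TW1_TABLE = [
    (-3.90, 0.99),
    (-3.18, 0.95),
    (-2.78, 0.90),
    (-1.91, 0.70),
    (-1.27, 0.50),
    (-0.59, 0.30),
    (0.45, 0.10),
    (0.9793, 0.05),
    (2.0234, 0.01),
    (3.2724, 0.001),
]


def tw1_pvalue(stat: float) -> float:
    """Upper-tail P for a TW1 statistic by interpolation in the table."""
    xs = [x for x, _ in _TW1_TABLE]
    ps = [p for _, p in _TW1_TABLE]
    if stat <= xs[0]:
        return ps[0]
    if stat >= xs[-1]:
        return ps[-1]
    for k in range(len(xs) - 1):
        if xs[k] <= stat <= xs[k + 1]:
            # log-linear in the tail probability
            f = (stat - xs[k]) / (xs[k + 1] - xs[k])
            return float(math.exp((1 - f) * math.log(ps[k]) + f * math.log(ps[k + 1])))
    return ps[-1]  # pragma: no cover


@dataclass
class StructureReport:
    eigenvalues: np.ndarray
    tw_statistic: float
    tw_pvalue: float
    significant: bool
    n_components: int
    n_variants_used: int


def pca_structure_check(geno: DosageMatrix, n_components: int = 10,
                        alpha: float = 0.05) -> StructureReport:
    """PCA of standardized dosages plus a Tracy–Widom check on the lead PC.

    Each variant is centered by its mean dosage and scaled by
    sqrt(p(1-p)) with p the estimated allele frequency; the top
    eigenvalues of the individual-by-individual covariance are reported
    together with the TW1 statistic of the leading one under moment
    (effective-marker) normalization.  ``significant`` means structure at
    level ``alpha``.
    """
    if geno.n_individuals < 2 or geno.n_variants < 2:
        raise ValueError("need at least 2 individuals and 2 variants")
    x = geno.imputed_dosages()
    p_hat = x.mean(axis=0) / 2.0
    keep = (p_hat > 0) & (p_hat < 1)
    x = x[:, keep]
    p_hat = p_hat[keep]
    if x.shape[1] < 2:
        raise ValueError("fewer than 2 polymorphic variants after dropping "
                         "zero-variance columns")
    x = (x - 2 * p_hat) / np.sqrt(2 * p_hat * (1 - p_hat))
    n, m = x.shape
    cov = x @ x.T / m
    eig = np.linalg.eigvalsh(cov)[::-1]
    eig = np.clip(eig, 0, None)
    nz = eig[: min(n - 1, m)]
    s1 = nz.sum()
    s2 = (nz ** 2).sum()
    # effective number of markers from the first two spectral moments
    n_eff = (n + 1) * s1 ** 2 / ((n - 1) * s2 - s1 ** 2)
    n_eff = max(n_eff, 2.0)
    ell = (n - 1) * nz[0] / s1
    a, b = math.sqrt(n_eff - 1), math.sqrt(float(n))
    mu = (a + b) ** 2 / n_eff
    sigma = (a + b) / n_eff * (1.0 / a + 1.0 / b) ** (1.0 / 3.0)
    tw = (ell - mu) / sigma
    p = tw1_pvalue(tw)
    return StructureReport(eigenvalues=eig[:n_components], tw_statistic=float(tw),
                           tw_pvalue=p, significant=bool(p < alpha),
                           n_components=min(n_components, len(eig)),
                           n_variants_used=m)
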