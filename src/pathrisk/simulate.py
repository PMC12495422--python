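"""Synthetic inputs with the statistical structure the pipeline assumes.

Every generator is fully deterministic under ``SimConfig.seed`` (each
stage draws from its own spawned stream, so calling order never matters).
The emulated world: unlinked HWE genotypes; sparse per-gene eQTL weight
models, a subset of which ("coupled" genes) load on the causal risk
variants so that predicted expression — and hence the pathway scores of
sets enriched for coupled genes — depends on the true risk score; GWAS
summary statistics sharing those causal variants; gene sets of sizes
2–300 with planted risk-associated sets and optional blocks of
gene-sharing sets (correlated pathway scores, for factor-model recovery);
and case/control plus ordinal Braak-like (0–6) and Thal-like (0–5) stages
whose Spearman correlation with the true risk score is calibrated to a
target (default 0.5).
"""

from __future__ import annotations

import functools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

from .containers import DosageMatrix, GeneSetCollection, ScoreMatrix

# non-ambiguous ref/alt pairs only: allele flips are exercised as REF/ALT
# swaps, which must not collide with the A/T-C/G ambiguity filter
_ALLELE_PAIRS = [("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"),
                 ("G", "A"), ("G", "T"), ("T", "C"), ("T", "G")]


@dataclass
class SimConfig:
    n_individuals: int = 173
    n_variants: int = 2000
    n_genes: int = 400
    n_gene_sets: int = 100
    maf_range: tuple = (0.05, 0.5)
    n_causal_variants: int = 50
    effect_size_sd: float = 0.5
    planted_set_fraction: float = 0.04
    target_phenotype_rho: float = 0.5
    factor_block_sizes: tuple = ()
    seed: int = 0

    def __post_init__(self):
        if self.n_individuals < 1 or self.n_variants < 1:
            raise ValueError("need at least one individual and one variant")
        if self.n_genes < 1 or self.n_gene_sets < 0:
            raise ValueError("invalid gene / gene-set counts")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        if self.n_causal_variants > self.n_variants:
            raise ValueError("n_causal_variants exceeds n_variants")
        if not 0 <= self.planted_set_fraction <= 1:
            raise ValueError("planted_set_fraction must be in [0, 1]")
        if not 0 <= self.target_phenotype_rho <= 1:
            raise ValueError("target_phenotype_rho must be in [0, 1]")
        if any(b < 2 for b in self.factor_block_sizes):
            raise ValueError("factor blocks need at least 2 sets each")

    def rng(self, stage: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([self.seed, stage]))


@dataclass
class SimTruth:
    causal_variant_ids: set
    true_prs: pd.Series
    planted_set_ids: set = field(default_factory=set)
    factor_assignment: dict = field(default_factory=dict)
    coupled_genes: set = field(default_factory=set)
    true_betas: pd.Series = None


def generate_genotypes(cfg: SimConfig, n_populations: int = 1,
                       fst: float = 0.0) -> DosageMatrix:
    """Unlinked HWE genotypes: per-variant MAF uniform in ``maf_range``,
    dosage Binomial(2, MAF) independently per individual.

    ``n_populations=2`` with ``fst > 0`` draws subpopulation frequencies
    from a Balding–Nichols model — used only to exercise the
    Tracy–Widom structure check.
    """
    rng = cfg.rng(1)
    lo, hi = cfg.maf_range
    maf = rng.uniform(lo, hi, cfg.n_variants)
    if n_populations == 1 or fst == 0.0:
        dosages = rng.binomial(2, maf, (cfg.n_individuals, cfg.n_variants))
    elif n_populations == 2:
        a = maf * (1 - fst) / fst
        b = (1 - maf) * (1 - fst) / fst
        p1 = np.clip(rng.beta(a, b), 1e-4, 1 - 1e-4)
        p2 = np.clip(rng.beta(a, b), 1e-4, 1 - 1e-4)
        half = cfg.n_individuals // 2
        dosages = np.vstack([
            rng.binomial(2, p1, (half, cfg.n_variants)),
            rng.binomial(2, p2, (cfg.n_individuals - half, cfg.n_variants)),
        ])
    else:
        raise ValueError("n_populations must be 1 or 2")
    pairs = [_ALLELE_PAIRS[i] for i in rng.integers(len(_ALLELE_PAIRS),
                                                    size=cfg.n_variants)]
    width = len(str(cfg.n_variants))
    variants = pd.DataFrame({
        "id": [f"snp{i + 1:0{width}d}" for i in range(cfg.n_variants)],
        "chrom": "1",
        "pos": 1 + 100 * np.arange(cfg.n_variants),
        "ref": [p[0] for p in pairs],
        "alt": [p[1] for p in pairs],
    })
    individuals = [f"ind{i + 1:04d}" for i in range(cfg.n_individuals)]
    return DosageMatrix(individuals, variants, dosages.astype(float))


def causal_variants(cfg: SimConfig, geno: DosageMatrix) -> pd.Series:
    """True per-variant effect sizes: N(0, effect_size_sd^2) on a random
    subset of ``n_causal_variants`` variants (deterministic in cfg)."""
    rng = cfg.rng(2)
    idx = np.sort(rng.choice(geno.n_variants, cfg.n_causal_variants,
                             replace=False))
    betas = rng.normal(0.0, cfg.effect_size_sd, cfg.n_causal_variants)
    ids = geno.variants["id"].iloc[idx]
    return pd.Series(betas, index=list(ids))


def true_prs(cfg: SimConfig, geno: DosageMatrix) -> pd.Series:
    """Standardized risk score from the true causal effects."""
    betas = causal_variants(cfg, geno)
    cols = [i for i, vid in enumerate(geno.variants["id"]) if vid in betas.index]
    raw = geno.dosages[:, cols] @ betas.loc[geno.variants["id"].iloc[cols]].to_numpy()
    raw = (raw - raw.mean()) / (raw.std() if raw.std() > 0 else 1.0)
    return pd.Series(raw, index=geno.individuals)


def generate_weight_models(cfg: SimConfig, geno: DosageMatrix,
                           coupled_gene_fraction: float = 0.3,
                           n_coupled_causal: int = 4,
                           background_weight_sd: float = 0.25,
                           tissue: str = "region1"
                           ) -> tuple[pd.DataFrame, set]:
    """Sparse per-gene weight models; a subset of genes loads on the causal
    variants with weights aligned to the causal effect signs, so their
    predicted expression rises with the true risk score.

    Returns (weight table, coupled gene ids).
    """
    if cfg.n_genes > 10 * cfg.n_variants:
        raise ValueError("more genes than can be assigned variants")
    rng = cfg.rng(4)
    betas = causal_variants(cfg, geno)
    causal_ids = list(betas.index)
    other_ids = [v for v in geno.variants["id"] if v not in betas.index]
    n_coupled = int(round(coupled_gene_fraction * cfg.n_genes))
    width = len(str(cfg.n_genes))
    gene_ids = [f"gene{i + 1:0{width}d}" for i in range(cfg.n_genes)]
    coupled = set(rng.choice(gene_ids, n_coupled, replace=False))
    rows = []
    for gene in gene_ids:
        if gene in coupled:
            nc = min(n_coupled_causal, len(causal_ids))
            for vid in rng.choice(causal_ids, nc, replace=False):
                align = 0.8 + 0.4 * rng.uniform()
                rows.append((gene, vid, align * betas[vid] / cfg.effect_size_sd))
            n_bg = int(rng.integers(1, 7))
        else:
            n_bg = int(rng.integers(1, 11))
        for vid in rng.choice(other_ids, min(n_bg, len(other_ids)), replace=False):
            rows.append((gene, vid, rng.normal(0.0, background_weight_sd)))
    vmeta = geno.variants.set_index("id")
    table = pd.DataFrame(rows, columns=["gene", "variant", "weight"])
    table["effect_allele"] = vmeta.loc[table["variant"], "alt"].to_numpy()
    table["noneffect_allele"] = vmeta.loc[table["variant"], "ref"].to_numpy()
    table["tissue"] = tissue
    return table[["gene", "variant", "effect_allele", "noneffect_allele",
                  "weight", "tissue"]], coupled


def generate_gwas_summary(cfg: SimConfig, geno: DosageMatrix,
                          flip_fraction: float = 0.0,
                          noise_sd_fraction: float = 0.1,
                          null_noise_sd: float = 0.0,
                          exclude_from_noise=()) -> pd.DataFrame:
    """Summary statistics sharing the causal variants with the truth.

    Causal variants carry the true effect plus Gaussian estimation noise;
    the rest are zero (plus optional ``null_noise_sd``).  A fraction of
    records is emitted with REF/ALT swapped and the effect sign inverted,
    to exercise harmonization; flipped ids are in attrs["flipped"].

    ``exclude_from_noise`` keeps the optional noise effects off the named
    variants.  A pure-null world must place them outside every weight
    model: the risk score and the predicted expression are both linear in
    the same genotypes, so noise effects on model variants would induce a
    real (if weak) dependence between the two.
    """
    rng = cfg.rng(5)
    betas = causal_variants(cfg, geno)
    beta = np.zeros(geno.n_variants)
    is_causal = geno.variants["id"].isin(betas.index).to_numpy()
    beta[is_causal] = betas.loc[geno.variants["id"][is_causal]].to_numpy()
    beta[is_causal] += rng.normal(0, noise_sd_fraction * cfg.effect_size_sd,
                                  is_causal.sum())
    if null_noise_sd > 0:
        eligible = ~is_causal
        if len(exclude_from_noise):
            eligible &= ~geno.variants["id"].isin(set(exclude_from_noise)).to_numpy()
        beta[eligible] = rng.normal(0, null_noise_sd, eligible.sum())
    se = np.full(geno.n_variants, 0.02)
    z = beta / se
    p = np.clip(2 * scipy.stats.norm.sf(np.abs(z)), 1e-300, 1.0)
    a1 = geno.variants["alt"].to_numpy().copy()
    a2 = geno.variants["ref"].to_numpy().copy()
    flipped = rng.uniform(size=geno.n_variants) < flip_fraction
    a1[flipped], a2[flipped] = a2[flipped], a1[flipped].copy()
    beta = np.where(flipped, -beta, beta)
    out = pd.DataFrame({"variant": geno.variants["id"], "a1": a1, "a2": a2,
                        "beta": beta, "se": se, "p": p})
    out.attrs["flipped"] = set(geno.variants["id"][flipped])
    return out


def generate_gene_sets(cfg: SimConfig, genes: list, coupled_genes=(),
                       planted_coupled_fraction: float = 0.8,
                       block_core_size: int = 30,
                       block_overlap: float = 0.8
                       ) -> tuple[GeneSetCollection, set, dict]:
    """Gene sets with planted risk-associated sets and gene-sharing blocks.

    Planted sets draw ``planted_coupled_fraction`` of their members from
    the coupled genes (>= 50% by construction); blocks of
    ``factor_block_sizes`` sets share ``block_overlap`` of their members
    with a common core, producing correlated pathway scores.  Remaining
    sets get log-uniform sizes spanning 2 to min(300, universe).

    Returns (collection, planted set names, {set name: block index}).
    """
    genes = list(genes)
    if len(genes) < 2:
        raise ValueError("gene universe too small for gene sets")
    coupled = [g for g in coupled_genes if g in set(genes)]
    uncoupled = [g for g in genes if g not in set(coupled)]
    rng = cfg.rng(6)
    max_size = min(300, len(genes))
    n_planted = int(round(cfg.planted_set_fraction * cfg.n_gene_sets))
    n_block = sum(cfg.factor_block_sizes)
    if n_planted + n_block > cfg.n_gene_sets:
        raise ValueError("planted + block sets exceed n_gene_sets")
    sets: dict[str, list] = {}
    planted_ids: set = set()
    blocks: dict[str, int] = {}

    def name(i, kind):
        return f"SIM ~ SET{i + 1:04d} ~ synthetic {kind} pathway {i + 1}"

    idx = 0
    for _ in range(n_planted):
        size = int(rng.integers(10, 31))
        n_c = min(int(round(planted_coupled_fraction * size)), len(coupled))
        members = list(rng.choice(coupled, n_c, replace=False))
        members += list(rng.choice(uncoupled, size - n_c, replace=False))
        nm = name(idx, "planted")
        sets[nm] = members
        planted_ids.add(nm)
        idx += 1
    for b, bsize in enumerate(cfg.factor_block_sizes):
        core = list(rng.choice(uncoupled, min(block_core_size, len(uncoupled)),
                               replace=False))
        for _ in range(bsize):
            size = int(rng.integers(10, 41))
            n_core = min(int(round(block_overlap * size)), len(core))
            members = list(rng.choice(core, n_core, replace=False))
            pool = [g for g in uncoupled if g not in set(members)]
            members += list(rng.choice(pool, min(size - n_core, len(pool)),
                                       replace=False))
            nm = name(idx, f"block{b + 1}")
            sets[nm] = members
            blocks[nm] = b
            idx += 1
    while idx < cfg.n_gene_sets:
        size = int(round(math.exp(rng.uniform(math.log(2), math.log(max_size)))))
        size = max(2, min(size, max_size))
        sets[name(idx, "random")] = list(rng.choice(genes, size, replace=False))
        idx += 1
    return GeneSetCollection(sets), planted_ids, blocks


def _discretization_attenuation(levels: int | None, rho_latent: float) -> float:
    """Spearman correlation between a latent normal and a noisy,
    possibly discretized copy, by deterministic large-sample simulation."""
    rng = np.random.default_rng(np.random.SeedSequence([987654321, levels or 0]))
    n = 40000
    z = rng.normal(size=n)
    w = rho_latent * z + math.sqrt(max(0.0, 1 - rho_latent ** 2)) * rng.normal(size=n)
    if levels is not None:
        qs = np.quantile(w, np.linspace(0, 1, levels + 1)[1:-1])
        w = np.digitize(w, qs)
    return float(scipy.stats.spearmanr(z, w).statistic)


@functools.lru_cache(maxsize=64)
def _calibrate_latent_rho(target: float, levels: int | None) -> float:
    """Latent Pearson correlation needed so that Spearman(latent,
    discretized noisy copy) hits the target (bisection on the simulated
    attenuation curve)."""
    if target <= 0:
        return 0.0
    lo, hi = 0.0, 1.0
    for _ in range(25):
        mid = 0.5 * (lo + hi)
        if _discretization_attenuation(levels, mid) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def generate_phenotypes(cfg: SimConfig, truth: SimTruth) -> pd.DataFrame:
    """Binary group plus ordinal Braak-like (0–6) and Thal-like (0–5)
    stages from thresholding the true risk score plus calibrated noise.

    Each stage is a fixed quantile cut of a noisy latent copy of the
    standardized risk score; the noise level is calibrated so the Spearman
    correlation between the risk score and each stage is approximately
    ``target_phenotype_rho``.
    """
    rng = cfg.rng(7)
    z = truth.true_prs.to_numpy()
    z = (z - z.mean()) / (z.std() if z.std() > 0 else 1.0)
    n = len(z)
    out = {}
    for col, levels in (("group", 2), ("braak", 7), ("thal", 6)):
        r = _calibrate_latent_rho(cfg.target_phenotype_rho, levels)
        if cfg.target_phenotype_rho >= 1.0:
            w = z.copy()
        else:
            w = r * z + math.sqrt(max(0.0, 1 - r ** 2)) * rng.normal(size=n)
        qs = np.quantile(w, np.linspace(0, 1, levels + 1)[1:-1])
        out[col] = np.digitize(w, qs)
    return pd.DataFrame(out, index=list(truth.true_prs.index))


@dataclass
class SimBundle:
    config: SimConfig
    genotypes: DosageMatrix
    weights: pd.DataFrame
    summary: pd.DataFrame
    gene_sets: GeneSetCollection
    phenotypes: pd.DataFrame
    truth: SimTruth


def simulate_all(cfg: SimConfig, flip_fraction: float = 0.0,
                 coupled_gene_fraction: float = 0.3,
                 null_noise_sd: float = 0.0) -> SimBundle:
    """Generate every pipeline input from one config.

    A pure-null world is ``n_causal_variants=0, planted_set_fraction=0``
    with ``null_noise_sd > 0`` so the risk score is nonconstant noise,
    independent of every pathway score.
    """
    geno = generate_genotypes(cfg)
    betas = causal_variants(cfg, geno)
    weights, coupled = generate_weight_models(
        cfg, geno, coupled_gene_fraction=coupled_gene_fraction)
    summary = generate_gwas_summary(
        cfg, geno, flip_fraction=flip_fraction, null_noise_sd=null_noise_sd,
        exclude_from_noise=set(weights["variant"]) if null_noise_sd > 0 else ())
    genes = sorted(weights["gene"].unique())
    sets, planted, blocks = generate_gene_sets(cfg, genes, coupled)
    truth = SimTruth(causal_variant_ids=set(betas.index),
                     true_prs=true_prs(cfg, geno),
                     planted_set_ids=planted,
                     factor_assignment=blocks,
                     coupled_genes=coupled,
                     true_betas=betas)
    pheno = generate_phenotypes(cfg, truth)
    return SimBundle(cfg, geno, weights, summary, sets, pheno, truth)


def generate_pathway_testbed(n_pathways: int, n_planted: int,
                             n_individuals: int,
                             dependence: str = "linear",
                             strength: float = 0.5,
                             seed: int = 0,
                             n_quadratic: int = 0,
                             quadratic_strength: float | None = None
                             ) -> tuple[pd.Series, ScoreMatrix, set]:
    """Association-stage testbed: a risk score plus pathway scores with a
    planted dependence.

    Linear planted rows are strength * z + noise; quadratic rows (the
    non-monotone variant a rank-correlation caller cannot see) are
    strength * (z^2 - 1)/sqrt(2) + noise.  ``n_quadratic`` of the
    ``n_planted`` rows use the quadratic form when dependence="mixed";
    dependence="linear"/"quadratic" makes all planted rows that type.
    Quadratic dependence carries its signal in the distribution tails, so
    it needs a larger variance share to survive winsorization;
    ``quadratic_strength`` (default 0.8) sets it separately.
    """
    if quadratic_strength is None:
        quadratic_strength = 0.8
    if n_planted > n_pathways:
        raise ValueError("more planted pathways than pathways")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 99]))
    z = rng.normal(size=n_individuals)
    scores = rng.normal(size=(n_pathways, n_individuals))
    if dependence == "linear":
        kinds = ["linear"] * n_planted
    elif dependence == "quadratic":
        kinds = ["quadratic"] * n_planted
    elif dependence == "mixed":
        kinds = ["quadratic"] * n_quadratic + ["linear"] * (n_planted - n_quadratic)
    else:
        raise ValueError("dependence must be linear, quadratic or mixed")
    for i, kind in enumerate(kinds):
        s = strength if kind == "linear" else quadratic_strength
        signal = z if kind == "linear" else (z ** 2 - 1) / math.sqrt(2)
        noise = math.sqrt(max(0.0, 1 - s ** 2))
        scores[i] = s * signal + noise * rng.normal(size=n_individuals)
    names = [f"SIM ~ SET{i + 1:04d} ~ testbed pathway {i + 1}"
             for i in range(n_pathways)]
    individuals = [f"ind{i + 1:04d}" for i in range(n_individuals)]
    mat = ScoreMatrix(pd.DataFrame(scores, index=names, columns=individuals),
                      n_used=pd.Series(1, index=names))
    planted = set(names[:n_planted])
    mat.planted_kinds = dict(zip(names[:n_planted], kinds))
    return pd.Series(z, index=individuals), mat, planted
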