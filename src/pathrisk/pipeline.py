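"""End-to-end driver: simulate -> QC -> GReX -> ssGSVA -> PRS -> HHG -> SEM.

Writes every stage's tables as TSV under an output directory; two runs
with the same config produce byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from . import io
from .association import consistency_check, region_association
from .genotype import pca_structure_check, qc_genotypes
from .grex import predict_expression
from .prs import harmonize, phenotype_correlation, score_prs
from .sem import (NoAdmissibleModelError, deduplicate_scores, efa_removal_loop,
                  factorability, fit_cfa, reattach_duplicates)
from .simulate import SimConfig, simulate_all
from .ssgsva import (filter_gene_sets, group_score_comparison,
                     high_ratio_fraction, ssgsva_scores)


def run_pipeline(cfg: SimConfig, outdir, mode: str = "broad",
                 min_perms: int = 1000, max_perms: int = 10000,
                 stop_extreme: int = 15, trim: float = 0.2,
                 sem_min_pathways: int = 4) -> dict:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle = simulate_all(cfg)
    io.write_vcf(bundle.genotypes, outdir / "genotypes.vcf")
    io.write_weights(bundle.weights, outdir / "weights.tsv")
    io.write_summary(bundle.summary, outdir / "summary.tsv")
    io.write_gmt(bundle.gene_sets, outdir / "gene_sets.gmt")
    io.write_phenotypes(bundle.phenotypes, outdir / "phenotypes.tsv")

    geno, qc_report = qc_genotypes(bundle.genotypes)
    qc_report.to_frame().to_csv(outdir / "qc_report.tsv", sep="\t", index=False)
    structure = pca_structure_check(geno)

    expr = predict_expression(geno, bundle.weights)
    io.write_scores(expr, outdir / "expression.tsv")

    sets = filter_gene_sets(bundle.gene_sets, expr, mode=mode)
    scores = ssgsva_scores(expr, sets)
    io.write_scores(scores, outdir / "pathway_scores.tsv")

    harmonized = harmonize(bundle.summary, geno)
    prs = score_prs(geno, harmonized)
    io.write_prs(prs.scores, outdir / "prs.tsv")
    pheno_corr = phenotype_correlation(prs, bundle.phenotypes)
    pheno_corr.to_csv(outdir / "phenotype_correlations.tsv", sep="\t")
    # high/low risk split at zero; a simulated score can land entirely on
    # one side, in which case fall back to a median split
    labels = (prs.scores.to_numpy() > 0).astype(int)
    if labels.min() == labels.max():
        labels = (prs.scores.to_numpy() > prs.scores.median()).astype(int)
    high_low = group_score_comparison(scores, labels)

    assoc = region_association(prs.scores, scores, region=scores.label or "region1",
                               trim=trim, min_perms=min_perms,
                               max_perms=max_perms, stop_extreme=stop_extreme,
                               seed=cfg.seed)
    assoc.drop(columns=[], errors="ignore").to_csv(
        outdir / "association.tsv", sep="\t", float_format="%.10g")
    consistency = consistency_check(assoc.attrs["records"])

    sig = assoc.index[assoc["significant"]]
    sem_summary: dict = {"fitted": False}
    if len(sig) >= sem_min_pathways:
        sub = pd.DataFrame(scores.values.loc[sig])
        from .containers import ScoreMatrix
        sub_scores = ScoreMatrix(sub, n_used=scores.n_used.loc[sig],
                                 label=scores.label)
        reduced, groups = deduplicate_scores(sub_scores, seed=cfg.seed)
        try:
            fac = factorability(reduced)
            solution = efa_removal_loop(reduced)
            model = fit_cfa(reduced, solution)
            model = reattach_duplicates(model, groups)
            model.loadings.to_csv(outdir / "sem_loadings.tsv", sep="\t",
                                  float_format="%.10g")
            model.phi.to_csv(outdir / "sem_factor_correlations.tsv", sep="\t",
                             float_format="%.10g")
            model.mod_indices.to_csv(outdir / "sem_modification_indices.tsv",
                                     sep="\t", index=False, float_format="%.10g")
            sem_summary = {"fitted": True, "n_factors": solution.n_factors,
                           "f_ml": model.f_ml, "kmo": fac["kmo"],
                           "bartlett_p": fac["bartlett_p"],
                           "converged": model.converged}
        except (NoAdmissibleModelError, ValueError) as exc:
            sem_summary = {"fitted": False, "reason": str(exc)}

    summary = {
        "n_individuals": geno.n_individuals,
        "n_variants_after_qc": geno.n_variants,
        "tw_statistic": structure.tw_statistic,
        "tw_significant": structure.significant,
        "n_genes_predicted": len(expr.features),
        "n_pathways_scored": len(scores.features),
        "high_ratio_fraction": high_ratio_fraction(sets, expr),
        "high_low_wilcoxon_p": high_low["pvalue"],
        "phenotype_rho": pheno_corr["rho"].to_dict(),
        "n_significant_pathways": int(assoc["significant"].sum()),
        "selected_empirical_p": assoc.attrs["region_threshold"].selected_empirical_p,
        "consistency_jaccard": consistency["jaccard"],
        "sem": sem_summary,
    }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
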