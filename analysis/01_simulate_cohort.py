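"""Generate the synthetic study cohort.

Writes a full input bundle — VCF genotypes, eQTL weight table, GWAS
summary statistics, GMT gene sets and phenotype table — for a cohort of
173 individuals with 50 causal risk variants, planted risk-associated
pathways and two blocks of gene-sharing pathways, under results/inputs/.
"""

from pathlib import Path

from pathrisk import io
from pathrisk.simulate import SimConfig, simulate_all

OUT = Path(__file__).resolve().parent.parent / "results" / "inputs"

CFG = SimConfig(n_individuals=173, n_variants=1500, n_genes=300,
                n_gene_sets=200, n_causal_variants=50,
                planted_set_fraction=0.05, target_phenotype_rho=0.5,
                factor_block_sizes=(6, 6), seed=20240901)


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    bundle = simulate_all(CFG, flip_fraction=0.05)
    io.write_vcf(bundle.genotypes, OUT / "genotypes.vcf")
    io.write_weights(bundle.weights, OUT / "weights.tsv")
    io.write_summary(bundle.summary, OUT / "summary.tsv")
    io.write_gmt(bundle.gene_sets, OUT / "gene_sets.gmt")
    io.write_phenotypes(bundle.phenotypes, OUT / "phenotypes.tsv")
    with open(OUT / "truth_planted_sets.txt", "w") as fh:
        fh.write("\n".join(sorted(bundle.truth.planted_set_ids)) + "\n")
    print(f"cohort: {CFG.n_individuals} individuals, {CFG.n_variants} variants, "
          f"{len(bundle.gene_sets)} gene sets "
          f"({len(bundle.truth.planted_set_ids)} planted risk-associated, "
          f"2 blocks of 6 gene-sharing sets)")
    print(f"inputs written to {OUT}")


if __name__ == "__main__":
    main()
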