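"""Predict genetically regulated expression from the eQTL weight models.

Expression of each gene is the weight model's linear combination of
effect-allele dosages; genes whose model variants were all removed by QC
are dropped and counted.
"""

from pathlib import Path

from pathrisk import io
from pathrisk.genotype import read_vcf
from pathrisk.grex import predict_expression

BASE = Path(__file__).resolve().parent.parent / "results"


def main():
    geno = read_vcf(BASE / "qc" / "genotypes_clean.vcf")
    weights = io.read_weights(BASE / "inputs" / "weights.tsv")
    expr = predict_expression(geno, weights)
    (BASE / "expression").mkdir(parents=True, exist_ok=True)
    io.write_scores(expr, BASE / "expression" / "grex.tsv")
    vals = expr.to_array()
    print(f"predicted {len(expr.features)} genes for "
          f"{len(expr.individuals)} individuals "
          f"(value range {vals.min():.2f} to {vals.max():.2f}; "
          f"{expr.n_skipped_absent} entries skipped as QC-removed)")


if __name__ == "__main__":
    main()
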