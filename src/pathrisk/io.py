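"""Readers and writers for the pipeline's on-disk formats.

VCF (v4.2, GT-only), GMT gene sets, and tab-delimited tables for eQTL
weight models, GWAS summary statistics, phenotypes, scores and risk
scores.  Reading of VCF lives in :mod:`pathrisk.genotype` (cyvcf2); this
module owns the plain-text writers and the simple tabular round-trips.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import DosageMatrix, GeneSetCollection, ScoreMatrix

SUMMARY_COLUMNS = ["variant", "a1", "a2", "beta", "se", "p"]
WEIGHT_COLUMNS = ["gene", "variant", "effect_allele", "noneffect_allele",
                  "weight", "tissue"]


def write_vcf(geno: DosageMatrix, path) -> None:
    """Write integer-valued dosages as a minimal VCF v4.2 with GT fields."""
    gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in pd.unique(geno.variants["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(geno.individuals) + "\n")
        for v in range(geno.n_variants):
            row = geno.variants.iloc[v]
            fields = [str(row["chrom"]), str(int(row["pos"])), str(row["id"]),
                      str(row["ref"]), str(row["alt"]), ".", "PASS", ".", "GT"]
            for i in range(geno.n_individuals):
                if geno.missing[i, v]:
                    fields.append("./.")
                else:
                    d = geno.dosages[i, v]
                    if d not in gt_map:
                        raise ValueError(
                            "only integer dosages (0/1/2) are VCF-writable")
                    fields.append(gt_map[d])
            fh.write("\t".join(fields) + "\n")


def read_gmt(path) -> GeneSetCollection:
    sets = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line: {line[:60]!r}")
            name, _desc, *genes = parts
            sets[name] = [g for g in genes if g]
    return GeneSetCollection(sets)


def write_gmt(sets: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, "na", *members]) + "\n")


def read_weights(path) -> pd.DataFrame:
    tbl = pd.read_csv(path, sep="\t", dtype={"gene": str, "variant": str})
    missing = set(WEIGHT_COLUMNS) - set(tbl.columns)
    if missing:
        raise ValueError(f"weight table missing columns {sorted(missing)}")
    return tbl[WEIGHT_COLUMNS]


def write_weights(weights: pd.DataFrame, path) -> None:
    weights[WEIGHT_COLUMNS].to_csv(path, sep="\t", index=False)


def read_summary(path) -> pd.DataFrame:
    tbl = pd.read_csv(path, sep="\t", dtype={"variant": str})
    missing = set(SUMMARY_COLUMNS) - set(tbl.columns)
    if missing:
        raise ValueError(f"summary table missing columns {sorted(missing)}")
    return tbl[SUMMARY_COLUMNS]


def write_summary(stats: pd.DataFrame, path) -> None:
    stats[SUMMARY_COLUMNS].to_csv(path, sep="\t", index=False)


def read_phenotypes(path) -> pd.DataFrame:
    tbl = pd.read_csv(path, sep="\t", dtype={"individual": str})
    return tbl.set_index("individual")


def write_phenotypes(pheno: pd.DataFrame, path) -> None:
    pheno.to_csv(path, sep="\t", index_label="individual")


def read_scores(path, label: str = "") -> ScoreMatrix:
    tbl = pd.read_csv(path, sep="\t", index_col=0)
    n_used = None
    if "n_used" in tbl.columns:
        n_used = tbl.pop("n_used")
    return ScoreMatrix(tbl, n_used=n_used, label=label)


def write_scores(scores: ScoreMatrix, path) -> None:
    out = scores.values.copy()
    out.insert(0, "n_used", scores.n_used)
    out.to_csv(path, sep="\t", index_label="feature",
               float_format="%.10g")


def read_prs(path) -> pd.Series:
    tbl = pd.read_csv(path, sep="\t", dtype={"individual": str})
    return tbl.set_index("individual")["score"]


def write_prs(scores: pd.Series, path) -> None:
    scores.rename("score").to_csv(path, sep="\t", index_label="individual",
                                  float_format="%.10g")
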