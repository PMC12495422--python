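"""VCF round-trip, QC filter battery, HWE exact test, structure check."""

import math

import numpy as np
import pandas as pd
import pytest

from pathrisk import io
from pathrisk.containers import DosageMatrix
from pathrisk.genotype import (hwe_exact_midp, pca_structure_check,
                               qc_genotypes, read_vcf)
from pathrisk.simulate import SimConfig, generate_genotypes


def test_vcf_round_trip(tmp_path, small_bundle):
    geno = small_bundle.genotypes
    path = tmp_path / "g.vcf"
    io.write_vcf(geno, path)
    back = read_vcf(path)
    assert back.individuals == geno.individuals
    assert list(back.variants["id"]) == list(geno.variants["id"])
    assert np.array_equal(back.dosages, geno.dosages)
    assert np.array_equal(back.missing, geno.missing)


def test_vcf_genotype_codes(tmp_path):
    path = tmp_path / "toy.vcf"
    path.write_text(
        "##fileformat=VCFv4.2\n"
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        "##contig=<ID=1>\n"
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ta\tb\tc\td\n"
        "1\t100\trs1\tA\tG\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\t./.\n"
        "1\t200\trs2\tA\tG,C\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\t0/0\n")
    geno = read_vcf(path)
    assert list(geno.variants["id"]) == ["rs1"]  # multiallelic skipped
    assert geno.n_skipped_records == 1
    assert list(geno.dosages[:, 0]) == [0.0, 1.0, 2.0, 0.0]
    assert list(geno.missing[:, 0]) == [False, False, False, True]


def test_hwe_midp_matches_enumeration_oracle():
    """Mid-P from the recurrence equals direct enumeration of the
    conditional distribution via log-factorials."""

    def oracle(het, hom1, hom2):
        n = het + hom1 + hom2
        rare = 2 * min(hom1, hom2) + het
        common = 2 * n - rare

        def logprob(h):
            a = (rare - h) // 2
            b = (common - h) // 2
            return (h * math.log(2) + math.lgamma(n + 1)
                    - math.lgamma(a + 1) - math.lgamma(b + 1)
                    - math.lgamma(h + 1))

        hs = [h for h in range(rare % 2, min(rare, common) + 1, 2)]
        logs = np.array([logprob(h) for h in hs])
        probs = np.exp(logs - logs.max())
        probs /= probs.sum()
        p_obs = probs[hs.index(het)]
        p = probs[probs <= p_obs * (1 + 1e-12)].sum()
        return min(1.0, p - 0.5 * p_obs)

    cases = [(6, 3, 3), (0, 6, 6), (11, 0, 0), (5, 20, 1), (2, 40, 0),
             (57, 50, 13), (1, 1, 1)]
    for het, h1, h2 in cases:
        assert hwe_exact_midp(het, h1, h2) == pytest.approx(
            oracle(het, h1, h2), rel=1e-9), (het, h1, h2)


def test_qc_counts_match_hand_enumeration(qc_fixture):
    clean, report = qc_genotypes(qc_fixture, t_geno=0.15, t_mind=0.3,
                                 t_maf=0.05, t_hwe=1e-3)
    assert report.removed == {
        "variant_missingness": 1, "individual_missingness": 1, "maf": 1,
        "hwe": 1, "strand_ambiguous": 1, "duplicate_id": 1}
    assert sorted(clean.variants["id"]) == ["v_clean", "v_dup"]
    assert clean.n_individuals == 11
    assert report.n_variants_out == 2


def test_qc_is_idempotent(qc_fixture):
    once, _ = qc_genotypes(qc_fixture, t_geno=0.15, t_mind=0.3,
                           t_maf=0.05, t_hwe=1e-3)
    twice, rep = qc_genotypes(once, t_geno=0.15, t_mind=0.3,
                              t_maf=0.05, t_hwe=1e-3)
    assert list(twice.variants["id"]) == list(once.variants["id"])
    assert np.array_equal(twice.dosages, once.dosages)
    assert all(v == 0 for v in rep.removed.values())


def test_filter_order_does_not_change_survivors(qc_fixture):
    """With individual filtering disabled the failing variants are
    non-interacting, so the surviving set equals the intersection of the
    per-filter pass sets applied independently."""
    clean, _ = qc_genotypes(qc_fixture, t_geno=0.15, t_mind=1.0,
                            t_maf=0.05, t_hwe=1e-3)
    ids = qc_fixture.variants["id"]
    pass_miss = set(ids[qc_fixture.missing.mean(axis=0) <= 0.15])
    af = np.ma.masked_array(qc_fixture.dosages, qc_fixture.missing).mean(axis=0) / 2
    maf = np.minimum(af, 1 - af)
    pass_maf = set(ids[np.asarray(maf) >= 0.05])
    hwe = []
    for v in range(qc_fixture.n_variants):
        ok = ~qc_fixture.missing[:, v]
        d = qc_fixture.dosages[ok, v]
        hwe.append(hwe_exact_midp(int((d == 1).sum()), int((d == 0).sum()),
                                  int((d == 2).sum())))
    pass_hwe = set(ids[np.array(hwe) >= 1e-3])
    pass_ambig = {i for i, r, a in zip(ids, qc_fixture.variants["ref"],
                                       qc_fixture.variants["alt"])
                  if (r, a) not in {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}}
    # both v_dup columns share one id, so set algebra already collapses the
    # duplicate exactly as the duplicate-id filter does
    expected = pass_miss & pass_maf & pass_hwe & pass_ambig
    assert set(clean.variants["id"]) == expected


def test_qc_errors():
    variants = pd.DataFrame({"id": ["v1"], "chrom": ["1"], "pos": [1],
                             "ref": ["A"], "alt": ["T"]})
    geno = DosageMatrix(["a", "b"], variants, np.array([[1.0], [1.0]]))
    with pytest.raises(ValueError, match="empty after QC"):
        qc_genotypes(geno)


def test_structure_check_null_vs_two_populations():
    sig = []
    for seed in range(10):
        cfg = SimConfig(n_individuals=100, n_variants=400,
                        n_causal_variants=0, seed=seed)
        rep = pca_structure_check(generate_genotypes(cfg))
        assert np.all(np.diff(rep.eigenvalues) <= 1e-9)
        sig.append(rep.significant)
    assert sum(sig) <= 1  # homogeneous: non-significant in >= 90% of seeds
    cfg = SimConfig(n_individuals=100, n_variants=400, n_causal_variants=0,
                    seed=0)
    stratified = generate_genotypes(cfg, n_populations=2, fst=0.15)
    rep = pca_structure_check(stratified)
    assert rep.significant
    assert rep.tw_statistic > 2.0


def test_structure_check_eigen_properties(small_bundle):
    geno = small_bundle.genotypes
    rep = pca_structure_check(geno, n_components=5)
    assert len(rep.eigenvalues) == 5
    assert np.all(np.diff(rep.eigenvalues) <= 1e-9)
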