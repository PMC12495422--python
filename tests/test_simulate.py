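"""Generator determinism, marginal structure and planted ground truth."""

import numpy as np
import pytest
import scipy.stats

from pathrisk.genotype import hwe_exact_midp
from pathrisk.simulate import (SimConfig, causal_variants, generate_gene_sets,
                               generate_genotypes, generate_gwas_summary,
                               generate_pathway_testbed, generate_phenotypes,
                               generate_weight_models, simulate_all, true_prs)


def test_same_seed_identical_everything():
    cfg = SimConfig(n_individuals=30, n_variants=80, n_genes=40,
                    n_gene_sets=10, n_causal_variants=10, seed=42)
    a = simulate_all(cfg, flip_fraction=0.2)
    b = simulate_all(cfg, flip_fraction=0.2)
    assert np.array_equal(a.genotypes.dosages, b.genotypes.dosages)
    assert a.weights.equals(b.weights)
    assert a.summary.drop(columns=[]).equals(b.summary)
    assert a.gene_sets.sets == b.gene_sets.sets
    assert a.phenotypes.equals(b.phenotypes)
    assert a.truth.planted_set_ids == b.truth.planted_set_ids


def test_symmetric_maf_centers_dosage_at_one():
    cfg = SimConfig(n_individuals=4000, n_variants=50,
                    maf_range=(0.5, 0.5), n_causal_variants=0, seed=1)
    geno = generate_genotypes(cfg)
    mean = geno.dosages.mean(axis=0)
    se = np.sqrt(0.5 / cfg.n_individuals)  # var of dosage = 2 p q = 0.5
    assert np.all(np.abs(mean - 1.0) < 3.5 * se + 0.02)


def test_hwe_holds_in_generated_genotypes():
    """Per-variant exact-test rejections stay near the nominal 5% because
    genotypes really are Binomial(2, MAF)."""
    cfg = SimConfig(n_individuals=200, n_variants=2000,
                    n_causal_variants=0, seed=2)
    geno = generate_genotypes(cfg)
    rej = 0
    for v in range(geno.n_variants):
        d = geno.dosages[:, v]
        p = hwe_exact_midp(int((d == 1).sum()), int((d == 0).sum()),
                           int((d == 2).sum()))
        rej += p < 0.05
    assert 0.02 < rej / geno.n_variants < 0.075


def test_weight_models_structure(small_bundle):
    w = small_bundle.weights
    truth = small_bundle.truth
    sizes = w.groupby("gene").size()
    assert sizes.min() >= 1
    assert (w.groupby("gene")["variant"].nunique() == sizes).all()
    # coupled genes put entries on causal variants, others never do
    on_causal = w[w["variant"].isin(truth.causal_variant_ids)]
    assert set(on_causal["gene"]) == truth.coupled_genes


def test_coupled_gene_expression_tracks_risk(small_bundle):
    from pathrisk.grex import predict_expression
    expr = predict_expression(small_bundle.genotypes, small_bundle.weights)
    z = small_bundle.truth.true_prs
    coupled = [g for g in expr.features if g in small_bundle.truth.coupled_genes]
    rhos = [abs(scipy.stats.spearmanr(expr.values.loc[g], z).statistic)
            for g in coupled]
    other = [abs(scipy.stats.spearmanr(expr.values.loc[g], z).statistic)
             for g in expr.features if g not in small_bundle.truth.coupled_genes]
    assert np.mean(rhos) > np.mean(other) + 0.1


def test_gwas_flips_are_recoverable(small_bundle):
    from pathrisk.prs import harmonize
    stats = small_bundle.summary
    flipped = stats.attrs["flipped"]
    assert len(flipped) > 0
    harm = harmonize(stats, small_bundle.genotypes)
    merged = harm.set_index("variant")
    orig = stats.set_index("variant")
    for vid in list(flipped)[:20]:
        assert merged.at[vid, "beta"] == pytest.approx(-orig.at[vid, "beta"])
    unflipped = [v for v in merged.index if v not in flipped][:20]
    for vid in unflipped:
        assert merged.at[vid, "beta"] == pytest.approx(orig.at[vid, "beta"])


def test_null_effects_give_constant_prs():
    from pathrisk.prs import harmonize, score_prs
    cfg = SimConfig(n_individuals=40, n_variants=100, n_causal_variants=0,
                    planted_set_fraction=0.0, seed=3)
    geno = generate_genotypes(cfg)
    stats = generate_gwas_summary(cfg, geno)
    prs = score_prs(geno, harmonize(stats, geno))
    assert np.allclose(prs.scores, 0.0)


def test_prs_from_summary_recovers_truth_as_noise_vanishes():
    cfg = SimConfig(n_individuals=150, n_variants=400, n_causal_variants=40,
                    seed=4)
    geno = generate_genotypes(cfg)
    from pathrisk.prs import harmonize, score_prs
    stats = generate_gwas_summary(cfg, geno, noise_sd_fraction=1e-6)
    prs = score_prs(geno, harmonize(stats, geno))
    rho = scipy.stats.spearmanr(prs.scores, true_prs(cfg, geno)).statistic
    assert rho > 0.99


def test_gene_sets_planted_and_blocks(small_bundle):
    sets = small_bundle.gene_sets
    truth = small_bundle.truth
    sizes = [len(m) for _, m in sets.items()]
    assert min(sizes) >= 2 and max(sizes) <= 300
    for name in truth.planted_set_ids:
        members = sets[name]
        frac = len(set(members) & truth.coupled_genes) / len(members)
        assert frac >= 0.5
    # gene sharing: within-block Jaccard exceeds between-block
    blocks = truth.factor_assignment
    by_block = {}
    for nm, b in blocks.items():
        by_block.setdefault(b, []).append(set(sets[nm]))

    def jac(a, b):
        return len(a & b) / len(a | b)

    within = [jac(a, b) for mem in by_block.values()
              for i, a in enumerate(mem) for b in mem[i + 1:]]
    between = [jac(a, b) for a in by_block[0] for b in by_block[1]]
    assert np.mean(within) > np.mean(between)


def test_identical_membership_gives_identical_scores(small_bundle):
    from pathrisk.containers import GeneSetCollection
    from pathrisk.grex import predict_expression
    from pathrisk.ssgsva import ssgsva_scores
    expr = predict_expression(small_bundle.genotypes, small_bundle.weights)
    members = small_bundle.gene_sets[list(small_bundle.gene_sets)[0]]
    twins = GeneSetCollection({"a": members, "b": list(members)})
    scores = ssgsva_scores(expr, twins)
    assert np.array_equal(scores.values.loc["a"], scores.values.loc["b"])


def test_phenotype_calibration_hits_target():
    """Spearman(risk, stage) lands near the 0.5 target (pooled seeds)."""
    rhos = {"group": [], "braak": [], "thal": []}
    for seed in range(8):
        cfg = SimConfig(n_individuals=173, n_variants=300,
                        n_causal_variants=30, seed=seed)
        geno = generate_genotypes(cfg)
        truth_prs = true_prs(cfg, geno)
        from pathrisk.simulate import SimTruth
        truth = SimTruth(causal_variant_ids=set(), true_prs=truth_prs)
        pheno = generate_phenotypes(cfg, truth)
        for col in rhos:
            rhos[col].append(
                scipy.stats.spearmanr(truth_prs, pheno[col]).statistic)
    for col, vals in rhos.items():
        assert abs(np.mean(vals) - 0.5) < 0.1, col


def test_phenotype_limits_and_balance():
    cfg = SimConfig(n_individuals=200, n_variants=100, n_causal_variants=20,
                    target_phenotype_rho=1.0, seed=6)
    geno = generate_genotypes(cfg)
    from pathrisk.simulate import SimTruth
    truth = SimTruth(causal_variant_ids=set(), true_prs=true_prs(cfg, geno))
    pheno = generate_phenotypes(cfg, truth)
    # no-noise limit: stages are deterministic quantile cuts of the score
    rho = scipy.stats.spearmanr(truth.true_prs, pheno["braak"]).statistic
    assert rho > 0.97
    assert set(pheno["braak"]) <= set(range(7))
    assert set(pheno["thal"]) <= set(range(6))
    balance = pheno["group"].mean()
    assert 0.4 < balance < 0.6
    with pytest.raises(ValueError):
        SimConfig(target_phenotype_rho=1.5)


def test_config_validation():
    with pytest.raises(ValueError):
        SimConfig(n_individuals=0)
    with pytest.raises(ValueError):
        SimConfig(maf_range=(0.0, 0.5))
    with pytest.raises(ValueError):
        SimConfig(n_causal_variants=10, n_variants=5)


def test_testbed_dependence_shapes():
    prs, scores, planted = generate_pathway_testbed(
        30, 6, 150, dependence="mixed", n_quadratic=3, strength=0.6, seed=0)
    kinds = scores.planted_kinds
    for name in planted:
        r = scipy.stats.spearmanr(prs, scores.values.loc[name]).statistic
        if kinds[name] == "linear":
            assert abs(r) > 0.3
        else:  # non-monotone: rank correlation blind
            assert abs(r) < 0.3
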