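"""ssGSVA against the literal step-by-step oracle, plus its invariances."""

import numpy as np
import pandas as pd
import pytest

from pathrisk.containers import GeneSetCollection, ScoreMatrix
from pathrisk.reference import ssgsva_literal
from pathrisk.ssgsva import (filter_gene_sets, group_score_comparison,
                             high_ratio_fraction, ssgsva_scores)


def _expr(arr, genes=None):
    arr = np.asarray(arr, float)
    genes = genes or [f"g{i + 1}" for i in range(arr.shape[0])]
    cols = [f"i{j + 1}" for j in range(arr.shape[1])]
    return ScoreMatrix(pd.DataFrame(arr, index=genes, columns=cols))


def test_matches_literal_oracle_on_seeded_fixture():
    rng = np.random.default_rng(2024)
    expr = _expr(rng.normal(size=(4, 6)))
    sets = GeneSetCollection({"s1": ["g1", "g2"], "s2": ["g3", "g4", "g1"]})
    fast = ssgsva_scores(expr, sets).to_array()
    literal = ssgsva_literal(expr.to_array(), expr.features, sets.sets)
    assert np.allclose(fast, literal, atol=1e-10)


@pytest.mark.parametrize("trial", range(10))
def test_matches_oracle_with_ties_and_degenerate_genes(trial):
    rng = np.random.default_rng(trial)
    p, n = int(rng.integers(4, 9)), int(rng.integers(3, 8))
    x = rng.normal(size=(p, n))
    if trial % 2 == 0:
        x[0] = 1.5                       # zero-variance gene
    if trial % 3 == 0:
        x = np.round(x, 1)               # ties inside genes
    expr = _expr(x)
    members = list(rng.choice(expr.features, max(2, p // 2), replace=False))
    sets = GeneSetCollection({"s": members})
    fast = ssgsva_scores(expr, sets).to_array()
    literal = ssgsva_literal(x, expr.features, sets.sets)
    assert np.allclose(fast, literal, atol=1e-10)


def test_affine_invariance_and_duplicates():
    """Per-gene positive affine transforms leave scores exactly unchanged
    (the kernel bandwidth scales with the gene SD), and membership-identical
    sets score identically (50 random fixtures).

    Nonlinear monotone transforms are only approximately neutral: they
    reshape the kernel-CDF values and can swap the cross-gene ranking of
    near-tied genes, which is a property of the Gaussian-kernel variant
    itself.
    """
    rng = np.random.default_rng(7)
    for _ in range(50):
        p, n = int(rng.integers(5, 10)), int(rng.integers(4, 9))
        x = rng.normal(size=(p, n))
        expr = _expr(x)
        members = list(rng.choice(expr.features, 3, replace=False))
        sets = GeneSetCollection({"s": members, "twin": list(members)})
        base = ssgsva_scores(expr, sets)
        assert np.array_equal(base.values.loc["s"], base.values.loc["twin"])
        y = x.copy()
        for g in range(p):
            y[g] = (1.5 + g) * y[g] + 2.0 * g  # positive affine per gene
        transformed = ssgsva_scores(_expr(y), sets)
        assert np.allclose(base.to_array(), transformed.to_array(), atol=1e-9)


def test_scores_bounded_and_columns_permute(small_bundle):
    from pathrisk.grex import predict_expression
    expr = predict_expression(small_bundle.genotypes, small_bundle.weights)
    sets = filter_gene_sets(small_bundle.gene_sets, expr, mode="broad")
    scores = ssgsva_scores(expr, sets)
    arr = scores.to_array()
    assert arr.min() >= -1 - 1e-12 and arr.max() <= 1 + 1e-12
    perm = np.arange(arr.shape[1])[::-1]
    expr_p = ScoreMatrix(expr.values.iloc[:, perm], n_used=expr.n_used)
    scores_p = ssgsva_scores(expr_p, sets)
    assert np.allclose(scores_p.to_array(), arr[:, perm])


def test_filter_modes():
    sizes = {1: ["g1"], 2: ["g1", "g2"], 10: [f"g{i}" for i in range(1, 11)],
             300: [f"g{i}" for i in range(1, 301)],
             301: [f"g{i}" for i in range(1, 302)]}
    sets = GeneSetCollection({f"s{k}": v for k, v in sizes.items()})
    expr = _expr(np.random.default_rng(0).normal(size=(301, 4)),
                 genes=[f"g{i}" for i in range(1, 302)])
    broad = filter_gene_sets(sets, expr, mode="broad")
    assert set(broad.names()) == {"s2", "s10", "s300", "s301"}
    strict = filter_gene_sets(sets, expr, mode="strict")
    assert set(strict.names()) == {"s10", "s300"}
    with pytest.raises(ValueError):
        filter_gene_sets(sets, expr, mode="medium")


def test_filter_counts_after_intersection():
    sets = GeneSetCollection({"present": ["g1", "g2", "g3"],
                              "absent": ["x1", "x2", "x3"]})
    expr = _expr(np.random.default_rng(0).normal(size=(3, 4)),
                 genes=["g1", "g2", "g3"])
    kept = filter_gene_sets(sets, expr, mode="broad")
    assert kept.names() == ["present"]


def test_group_comparison_null_and_power():
    rng = np.random.default_rng(0)
    scores = ScoreMatrix(pd.DataFrame(rng.normal(size=(5, 40))))
    same = group_score_comparison(scores, np.repeat([0, 1], 20))
    assert same["pvalue"] > 0.01
    hits = 0
    for seed in range(20):
        rng = np.random.default_rng(seed)
        base = rng.normal(size=(5, 100))
        base[:, 50:] += 1.0  # 1 SD shift for the second group
        shifted = ScoreMatrix(pd.DataFrame(base))
        res = group_score_comparison(shifted, np.repeat([0, 1], 50))
        hits += res["pvalue"] < 0.05
    assert hits >= 19
    with pytest.raises(ValueError):
        group_score_comparison(scores, np.zeros(40))


def test_high_ratio_fraction_rule():
    expr = _expr(np.random.default_rng(0).normal(size=(9, 4)),
                 genes=[f"g{i}" for i in range(1, 10)])
    mk = lambda k, n: [f"g{i}" for i in range(1, k + 1)] + \
        [f"x{i}" for i in range(n - k)]
    sets = GeneSetCollection({"six_of_ten": mk(6, 10),
                              "five_of_ten": mk(5, 10),
                              "nine_of_ten": mk(9, 10)})
    assert high_ratio_fraction(sets, expr) == pytest.approx(2 / 3)
    with pytest.raises(ValueError):
        high_ratio_fraction(GeneSetCollection({}), expr)
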