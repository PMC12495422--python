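"""Deduplication, factorability, the EFA removal loop and the CFA fit."""

import numpy as np
import pandas as pd
import pytest

from pathrisk.containers import ScoreMatrix
from pathrisk.sem import (NoAdmissibleModelError, deduplicate_scores,
                          efa_removal_loop, factorability, fit_cfa,
                          fit_cfa_corr, kmo_bartlett, reattach_duplicates)


def _scores(arr, names=None):
    arr = np.asarray(arr, float)
    names = names or [f"p{i}" for i in range(arr.shape[0])]
    cols = [f"i{j}" for j in range(arr.shape[1])]
    return ScoreMatrix(pd.DataFrame(arr, index=names, columns=cols))


def _two_factor_data(n=500, lam=0.8, per_factor=4, phi=0.0, seed=0):
    rng = np.random.default_rng(seed)
    cov = np.array([[1.0, phi], [phi, 1.0]])
    z = rng.multivariate_normal([0, 0], cov, size=n).T
    resid = np.sqrt(1 - lam ** 2)
    rows = [lam * z[0] + resid * rng.normal(size=n) for _ in range(per_factor)]
    rows += [lam * z[1] + resid * rng.normal(size=n) for _ in range(per_factor)]
    return _scores(np.array(rows))


def test_deduplicate_identity_and_grouping():
    rng = np.random.default_rng(0)
    base = rng.normal(size=(4, 6))
    arr = np.vstack([base, base[1], base[1]])  # three copies of row 1
    scores = _scores(arr, names=["a", "b", "c", "d", "b2", "b3"])
    reduced, groups = deduplicate_scores(scores, seed=1)
    assert len(reduced.features) == 4
    (rep, members), = groups.items()
    assert sorted(members) == ["b", "b2", "b3"]
    assert rep in members
    # no duplicates -> identity
    clean = _scores(rng.normal(size=(3, 6)))
    reduced2, groups2 = deduplicate_scores(clean)
    assert reduced2.features == clean.features and groups2 == {}


def test_kmo_two_variables_is_half():
    rng = np.random.default_rng(0)
    z = rng.normal(size=40)
    scores = _scores(np.array([z + 0.5 * rng.normal(size=40),
                               z + 0.5 * rng.normal(size=40)]))
    assert factorability(scores)["kmo"] == pytest.approx(0.5)


def test_bartlett_identity_matrix():
    out = kmo_bartlett(np.eye(5), 30)
    assert out["bartlett_chi2"] == pytest.approx(0.0)
    assert out["bartlett_p"] == pytest.approx(1.0)
    assert out["bartlett_df"] == 10


def test_bartlett_hand_formula():
    # ranks (1..5) vs (2,4,1,3,5): Spearman exactly 0.5
    scores = _scores(np.array([[1, 2, 3, 4, 5], [2, 4, 1, 3, 5]], float))
    out = factorability(scores)
    expected = -(5 - 1 - (2 * 2 + 5) / 6) * np.log(1 - 0.25)
    assert out["bartlett_chi2"] == pytest.approx(expected)
    assert out["bartlett_df"] == 1


def test_efa_recovers_two_blocks():
    scores = _two_factor_data(n=400, lam=0.85, per_factor=4, seed=3)
    sol = efa_removal_loop(scores)
    assert sol.n_factors == 2
    assert sol.removed == []
    groups = {}
    for v, f in sol.assignment.items():
        groups.setdefault(f, set()).add(v)
    assert sorted(len(g) for g in groups.values()) == [4, 4]
    block1 = {f"p{i}" for i in range(4)}
    assert block1 in groups.values()


def test_efa_removes_uncorrelated_variable():
    rng = np.random.default_rng(4)
    scores = _two_factor_data(n=400, lam=0.85, per_factor=3, seed=4)
    noise = rng.normal(size=(1, 400))
    arr = np.vstack([scores.to_array(), noise])
    sol = efa_removal_loop(_scores(arr))
    removed_names = [v for v, _ in sol.removed]
    assert "p6" in removed_names  # the pure-noise variable
    assert sol.n_factors == 2


def test_efa_no_admissible_model():
    # mutually near-uncorrelated variables: the removal rules strip weak
    # loadings and single-variable factors until fewer than 2 remain
    rng = np.random.default_rng(4)
    arr = rng.normal(size=(4, 3000))
    with pytest.raises(NoAdmissibleModelError):
        efa_removal_loop(_scores(arr))


def test_cfa_perfect_fit_limit():
    lam = np.zeros((6, 2))
    lam[:3, 0] = 0.8
    lam[3:, 1] = 0.7
    phi = np.array([[1.0, 0.4], [0.4, 1.0]])
    theta = 1 - np.sum(lam ** 2, axis=1)
    sigma = lam @ phi @ lam.T + np.diag(theta)
    names = [f"v{i}" for i in range(6)]
    s = pd.DataFrame(sigma, index=names, columns=names)
    assignment = {v: (0 if i < 3 else 1) for i, v in enumerate(names)}
    model = fit_cfa_corr(s, assignment, 400)
    assert model.f_ml == pytest.approx(0.0, abs=1e-6)
    assert np.allclose(model.loadings["estimate"].to_numpy(),
                       [0.8] * 3 + [0.7] * 3, atol=1e-3)
    assert model.phi.iloc[0, 1] == pytest.approx(0.4, abs=1e-3)
    assert model.f_ml >= 0


def test_cfa_parameter_recovery_from_data():
    scores = _two_factor_data(n=500, lam=0.8, per_factor=4, phi=0.0, seed=6)
    sol = efa_removal_loop(scores)
    model = fit_cfa(scores, sol)
    assert model.converged
    assert (model.loadings["t"] > 2).all()
    assert abs(model.phi.iloc[0, 1]) < 0.1   # orthogonal truth
    max_t2 = (model.loadings["t"] ** 2).max()
    assert (model.mod_indices["mi"] < max_t2).all()


def test_reattach_round_trip():
    scores = _two_factor_data(n=300, lam=0.85, per_factor=3, seed=7)
    dup = np.vstack([scores.to_array(), scores.to_array()[0:1]])
    names = [f"p{i}" for i in range(6)] + ["p0_twin"]
    dup_scores = _scores(dup, names=names)
    dup_scores.values.loc["p0_twin"] = dup_scores.values.loc["p0"]
    reduced, groups = deduplicate_scores(dup_scores, seed=0)
    sol = efa_removal_loop(reduced)
    model = fit_cfa(reduced, sol)
    full = reattach_duplicates(model, groups)
    # every pre-dedup pathway assigned via its representative
    assert len(full.loadings) == len(sol.assignment) + sum(
        len(g) - 1 for g in groups.values())
    rep = [r for r, g in groups.items() if len(g) == 2]
    if rep:
        assert full.multiplicity[rep[0]] == 2
    retained = full.loadings["representative"].iloc[0]
    with pytest.raises(KeyError):
        reattach_duplicates(model, {retained: ["some_other_pathway"]})


def test_reattach_no_groups_is_identity():
    scores = _two_factor_data(n=300, lam=0.85, per_factor=3, seed=8)
    sol = efa_removal_loop(scores)
    model = fit_cfa(scores, sol)
    same = reattach_duplicates(model, {})
    assert list(same.loadings.index) == list(model.loadings.index)
    assert same.f_ml == model.f_ml
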