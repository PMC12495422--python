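"""Pathway-interaction modeling: factorability, EFA, and confirmatory SEM.

Identically scored pathways (a by-product of rank-based scoring over the
same expressed genes) are first collapsed to a seeded-random
representative.  Factorability is assessed with KMO and Bartlett's
sphericity test; exploratory structure comes from PCA of the Spearman
correlation matrix (eigenvalue > 1 extraction, varimax rotation) with
iterative removal of variables whose rotated loadings never reach the cut
(0.6) and of factors left with a single variable.  The confirmatory model
S ~ Sigma(theta) = Lambda Phi Lambda' + Theta is fitted by maximum
likelihood on the same Spearman matrix, with standard errors from the
inverse observed information and univariate score-test modification
indices for the fixed cross-loadings (reported, never auto-applied).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.optimize
import scipy.stats
from statsmodels.multivariate.factor_rotation import rotate_factors

from .containers import ScoreMatrix
from .ssgsva import duplicate_score_groups

logger = logging.getLogger("pathrisk")


class NoAdmissibleModelError(RuntimeError):
    """Raised when the removal loop leaves fewer than 2 variables."""


def deduplicate_scores(scores: ScoreMatrix, seed: int = 0
                       ) -> tuple[ScoreMatrix, dict]:
    """Collapse bitwise-identical score rows to one random representative.

    Returns the reduced matrix and {representative: [members]} for every
    group (including the representative itself), so the excluded pathways
    can be reattached to the fitted model later.
    """
    groups = duplicate_score_groups(scores)
    member_of = {m: first for first, members in groups.items() for m in members}
    rng = np.random.default_rng(seed)
    keep = []
    rep_groups = {}
    handled = set()
    for name in scores.features:
        if name in handled:
            continue
        first = member_of.get(name)
        if first is None:
            keep.append(name)
        else:
            grp = groups[first]
            rep = grp[rng.integers(len(grp))]
            keep.append(rep)
            rep_groups[rep] = list(grp)
            handled.update(grp)
    values = scores.values.loc[keep]
    reduced = ScoreMatrix(values, n_used=scores.n_used.loc[keep],
                          label=scores.label)
    return reduced, rep_groups


def _spearman_corr(scores: ScoreMatrix) -> pd.DataFrame:
    mat = scores.to_array()
    r = scipy.stats.spearmanr(mat, axis=1).statistic
    if np.isscalar(r):  # two variables
        r = np.array([[1.0, r], [r, 1.0]])
    return pd.DataFrame(r, index=scores.features, columns=scores.features)


def factorability(scores: ScoreMatrix, ridge: float = 1e-8) -> dict:
    """KMO sampling adequacy and Bartlett's sphericity test.

    Both are computed on the Spearman correlation matrix used by the CFA.
    With only two variables KMO is 0.5 by construction (the partial
    correlation equals the zero-order one).
    """
    p = len(scores.features)
    n = len(scores.individuals)
    if p < 2:
        raise ValueError("need at least 2 pathways")
    r = _spearman_corr(scores).to_numpy()
    return kmo_bartlett(r, n, ridge=ridge)


def kmo_bartlett(r: np.ndarray, n: int, ridge: float = 1e-8) -> dict:
    """KMO and Bartlett's test from a correlation matrix directly.

    KMO = sum r^2 / (sum r^2 + sum partial^2) over off-diagonal entries,
    partial correlations via the standardized inverse correlation matrix;
    Bartlett chi2 = -(n - 1 - (2p + 5)/6) ln|R| on p(p-1)/2 df.
    """
    r = np.asarray(r, float)
    p = r.shape[0]
    try:
        rinv = np.linalg.inv(r)
    except np.linalg.LinAlgError:
        logger.warning("singular correlation matrix; KMO uses a ridge-"
                       "regularized inverse")
        rinv = np.linalg.inv(r + ridge * np.eye(p))
    d = np.sqrt(np.diag(rinv))
    partial = -rinv / np.outer(d, d)
    off = ~np.eye(p, dtype=bool)
    ssr = (r[off] ** 2).sum()
    ssp = (partial[off] ** 2).sum()
    kmo = ssr / (ssr + ssp) if (ssr + ssp) > 0 else np.nan
    sign, logdet = np.linalg.slogdet(r)
    if sign <= 0:
        raise ValueError("Bartlett test undefined: |R| <= 0")
    chi2 = -(n - 1 - (2 * p + 5) / 6.0) * logdet
    df = p * (p - 1) // 2
    pval = float(scipy.stats.chi2.sf(chi2, df))
    return {"kmo": float(kmo), "bartlett_chi2": float(chi2),
            "bartlett_df": int(df), "bartlett_p": pval,
            "n_ge_p": bool(n > p)}


@dataclass
class FactorSolution:
    assignment: dict                # variable -> factor index
    loadings: pd.DataFrame          # variables x factors (rotated)
    eigenvalues: np.ndarray
    removed: list                   # (variable, reason)
    n_factors: int


def _pca_loadings(r: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    eig, vec = np.linalg.eigh(r)
    order = np.argsort(eig)[::-1]
    eig, vec = eig[order], vec[:, order]
    return eig, vec


def efa_removal_loop(scores: ScoreMatrix, loading_cut: float = 0.6
                     ) -> FactorSolution:
    """PCA factor extraction with the iterative low-loading removal rule.

    Repeat until stable: eigen-decompose the Spearman correlation matrix,
    keep components with eigenvalue > 1, form loadings eigvec*sqrt(eig),
    varimax-rotate, then delete every variable whose maximum absolute
    rotated loading is below ``loading_cut``.  Finally drop factors with a
    single assigned variable (removing their variables and re-looping).
    """
    variables = list(scores.features)
    removed: list = []
    corr_all = _spearman_corr(scores)
    while True:
        if len(variables) < 2:
            raise NoAdmissibleModelError(
                "fewer than 2 variables survive the removal loop")
        r = corr_all.loc[variables, variables].to_numpy()
        eig, vec = _pca_loadings(r)
        k = max(int((eig > 1.0).sum()), 1)
        load = vec[:, :k] * np.sqrt(np.clip(eig[:k], 0, None))
        if k > 1:
            load, _ = rotate_factors(load, "varimax")
        maxload = np.abs(load).max(axis=1)
        weak = [v for v, ml in zip(variables, maxload) if ml < loading_cut]
        if weak:
            removed += [(v, "max |loading| < cut") for v in weak]
            variables = [v for v in variables if v not in set(weak)]
            continue
        assign = {v: int(np.abs(load[i]).argmax())
                  for i, v in enumerate(variables)}
        counts = pd.Series(list(assign.values())).value_counts()
        lonely = counts[counts < 2].index
        if len(lonely):
            drop = [v for v, f in assign.items() if f in set(lonely)]
            removed += [(v, "single-variable factor") for v in drop]
            variables = [v for v in variables if v not in set(drop)]
            continue
        break
    factors = sorted(set(assign.values()))
    remap = {f: i for i, f in enumerate(factors)}
    # report only factors that kept variables, renumbered F1..Fm
    loadings = pd.DataFrame(load[:, factors], index=variables,
                            columns=[f"F{i + 1}" for i in range(len(factors))])
    return FactorSolution(
        assignment={v: remap[f] for v, f in assign.items()},
        loadings=loadings, eigenvalues=eig, removed=removed,
        n_factors=len(factors))


@dataclass
class SemModel:
    loadings: pd.DataFrame          # variable, factor, estimate, se, t
    phi: pd.DataFrame               # factor correlations
    theta: pd.Series                # residual variances
    f_ml: float
    chi2: float
    n: int
    mod_indices: pd.DataFrame       # variable, factor, mi (fixed loadings)
    converged: bool
    duplicate_groups: dict = field(default_factory=dict)
    multiplicity: pd.Series = None  # per reported pathway


def _pack(lam, phi_off, theta):
    return np.concatenate([lam, phi_off, theta])


def _unpack(params, p, k, pattern_rows, pattern_cols, tril):
    lam = np.zeros((p, k))
    nl = len(pattern_rows)
    lam[pattern_rows, pattern_cols] = params[:nl]
    phi = np.eye(k)
    off = params[nl:nl + len(tril[0])]
    phi[tril] = off
    phi[(tril[1], tril[0])] = off
    theta = params[nl + len(tril[0]):]
    return lam, phi, theta


def _f_ml(sigma: np.ndarray, s: np.ndarray, logdet_s: float) -> float:
    sign, logdet = np.linalg.slogdet(sigma)
    if sign <= 0:
        return np.inf  # line search backs off non-PD candidates
    return logdet + float(np.trace(np.linalg.solve(sigma, s))) - logdet_s - s.shape[0]


def fit_cfa(scores: ScoreMatrix, solution: FactorSolution,
            max_iter: int = 500, tol: float = 1e-6) -> SemModel:
    """Fit the confirmatory factor model by maximum likelihood.

    S is the Spearman correlation matrix of the retained variables; free
    parameters are the pattern loadings, the off-diagonal factor
    correlations (factor variances fixed to 1) and the diagonal residual
    variances.  Start: EFA loadings, Theta = 1 - communality, Phi = I.
    """
    variables = [v for v in scores.features if v in solution.assignment]
    s = _spearman_corr(ScoreMatrix(scores.values.loc[variables],
                                   n_used=scores.n_used.loc[variables]))
    pattern_cols = [solution.assignment[v] for v in variables]
    start = np.array([solution.loadings.loc[v].iloc[pattern_cols[i]]
                      if v in solution.loadings.index else 0.5
                      for i, v in enumerate(variables)])
    return fit_cfa_corr(s, solution.assignment, len(scores.individuals),
                        start_loadings=start, n_factors=solution.n_factors,
                        max_iter=max_iter, tol=tol)


def fit_cfa_corr(s: pd.DataFrame, assignment: dict, n_obs: int,
                 start_loadings=None, n_factors: int | None = None,
                 max_iter: int = 500, tol: float = 1e-6) -> SemModel:
    """ML confirmatory factor fit from a correlation matrix.

    Minimizes F_ML = ln|Sigma| + tr(S Sigma^-1) - ln|S| - p over the
    pattern loadings, factor correlations and residual variances.  SEs
    come from the inverse observed information of F_ML scaled by 2/(n-1);
    t = estimate / SE.  The modification index of each fixed cross-loading
    is the univariate score statistic (n-1) g^2 / h with g and h the F_ML
    gradient and information entry at the solution.
    """
    variables = [v for v in s.index if v in assignment]
    k = n_factors if n_factors is not None else (
        max(assignment[v] for v in variables) + 1)
    p = len(variables)
    n = n_obs
    s = s.loc[variables, variables].to_numpy(float)
    sign, logdet_s = np.linalg.slogdet(s)
    if sign <= 0:
        raise ValueError("sample correlation matrix is not positive definite")
    pattern_rows = np.arange(p)
    pattern_cols = np.array([assignment[v] for v in variables])
    tril = np.tril_indices(k, -1)

    if start_loadings is None:
        lam0 = np.full(p, 0.7)
    else:
        lam0 = np.asarray(start_loadings, float)
    theta0 = np.clip(1.0 - lam0 ** 2, 0.05, None)
    x0 = _pack(lam0, np.zeros(len(tril[0])), theta0)

    def objective(params):
        lam, phi, theta = _unpack(params, p, k, pattern_rows, pattern_cols, tril)
        sigma = lam @ phi @ lam.T + np.diag(theta)
        return _f_ml(sigma, s, logdet_s)

    nl = p
    bounds = ([(None, None)] * nl
              + [(-0.999, 0.999)] * len(tril[0])
              + [(1e-6, None)] * p)
    res = scipy.optimize.minimize(objective, x0, method="L-BFGS-B",
                                  bounds=bounds,
                                  options={"maxiter": max_iter, "ftol": tol})
    converged = bool(res.success)
    if not converged:
        logger.warning("CFA did not converge: %s", res.message)
    params = res.x
    f_val = float(res.fun)
    lam, phi, theta = _unpack(params, p, k, pattern_rows, pattern_cols, tril)

    # observed information of F_ML (numeric Hessian, central differences)
    def grad(params):
        return scipy.optimize.approx_fprime(params, objective, 1e-6)

    g0 = grad(params)
    npar = len(params)
    h = np.empty((npar, npar))
    step = 1e-5
    for j in range(npar):
        pj = params.copy()
        pj[j] += step
        h[:, j] = (grad(pj) - g0) / step
    h = (h + h.T) / 2
    try:
        cov = np.linalg.inv(h) * 2.0 / (n - 1)
        se_all = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se_all = np.full(npar, np.nan)
        converged = False
    se_lam = se_all[:nl]
    with np.errstate(divide="ignore", invalid="ignore"):
        t_lam = np.where(se_lam > 0, params[:nl] / se_lam, np.nan)

    # resolve factor sign indeterminacy: reflect any factor whose pattern
    # loadings sum negative (objective and SEs are invariant)
    est = params[:nl].copy()
    for f in range(k):
        sel = pattern_cols == f
        if sel.any() and est[sel].sum() < 0:
            est[sel] *= -1
            t_lam[sel] = np.negative(t_lam[sel])
            lam[:, f] *= -1  # keep Sigma identical for the MI evaluation
            phi[f, :] *= -1
            phi[:, f] *= -1
            phi[f, f] = 1.0
    loadings = pd.DataFrame({
        "variable": variables,
        "factor": [f"F{c + 1}" for c in pattern_cols],
        "estimate": est,
        "se": se_lam,
        "t": t_lam,
    }).set_index("variable")

    # modification indices for fixed cross-loadings
    mi_rows = []
    eps = 1e-5
    for i, v in enumerate(variables):
        for f in range(k):
            if f == pattern_cols[i]:
                continue

            def obj_cross(delta, i=i, f=f):
                lam2 = lam.copy()
                lam2[i, f] = delta
                sigma = lam2 @ phi @ lam2.T + np.diag(theta)
                return _f_ml(sigma, s, logdet_s)

            f0 = obj_cross(0.0)
            fp = obj_cross(eps)
            fm = obj_cross(-eps)
            g = (fp - fm) / (2 * eps)
            hh = (fp - 2 * f0 + fm) / eps ** 2
            mi = (n - 1) * g * g / hh if hh > 0 else 0.0
            mi_rows.append({"variable": v, "factor": f"F{f + 1}", "mi": mi})
    mod = pd.DataFrame(mi_rows, columns=["variable", "factor", "mi"])
    phi_df = pd.DataFrame(phi, index=[f"F{i+1}" for i in range(k)],
                          columns=[f"F{i+1}" for i in range(k)])
    return SemModel(loadings=loadings, phi=phi_df,
                    theta=pd.Series(theta, index=variables),
                    f_ml=f_val, chi2=(n - 1) * f_val, n=n,
                    mod_indices=mod, converged=converged)


def edge_list(model: SemModel) -> pd.DataFrame:
    """Diagram-ready edges: factor->pathway (loading, t, multiplicity)
    and factor<->factor (correlation) rows."""
    rows = []
    for v, rec in model.loadings.iterrows():
        mult = 1
        if model.multiplicity is not None and v in model.multiplicity.index:
            mult = int(model.multiplicity[v])
        rows.append({"source": rec["factor"], "target": v, "kind": "loading",
                     "value": rec["estimate"], "t": rec.get("t", np.nan),
                     "multiplicity": mult})
    for i, a in enumerate(model.phi.index):
        for b in model.phi.columns[i + 1:]:
            rows.append({"source": a, "target": b, "kind": "factor_correlation",
                         "value": model.phi.loc[a, b], "t": np.nan,
                         "multiplicity": 1})
    return pd.DataFrame(rows, columns=["source", "target", "kind", "value",
                                       "t", "multiplicity"])


def reattach_duplicates(model: SemModel, duplicate_groups: dict) -> SemModel:
    """Annotate the fitted model with the temporarily excluded pathways.

    Every member of a duplicate group inherits its representative's factor
    and loading; the representative carries the group multiplicity.
    """
    rows = []
    mult = {}
    for v in model.loadings.index:
        grp = duplicate_groups.get(v, [v])
        if v not in grp:
            raise KeyError(f"unknown representative {v!r} in duplicate groups")
        for member in grp:
            rec = model.loadings.loc[v].to_dict()
            rec["variable"] = member
            rec["representative"] = v
            rows.append(rec)
        mult[v] = len(grp)
    expanded = pd.DataFrame(rows).set_index("variable")
    out = SemModel(loadings=expanded, phi=model.phi, theta=model.theta,
                   f_ml=model.f_ml, chi2=model.chi2, n=model.n,
                   mod_indices=model.mod_indices, converged=model.converged,
                   duplicate_groups=duplicate_groups,
                   multiplicity=pd.Series(mult))
    return out
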