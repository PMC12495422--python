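"""Model interactions among the significant pathways by factor analysis.

Pathways with identical score vectors are collapsed to one seeded-random
representative; factorability is checked (KMO, Bartlett); the EFA removal
loop extracts eigenvalue>1 components with varimax rotation, deleting
variables whose loadings never reach 0.6 and single-variable factors; the
resulting structure is fitted as a confirmatory factor model by maximum
likelihood, and the temporarily excluded duplicates are reattached.
"""

from pathlib import Path

import pandas as pd

from pathrisk import io
from pathrisk.containers import ScoreMatrix
from pathrisk.sem import (NoAdmissibleModelError, deduplicate_scores,
                          edge_list, efa_removal_loop, factorability,
                          fit_cfa, reattach_duplicates)

BASE = Path(__file__).resolve().parent.parent / "results"


def main():
    assoc = pd.read_csv(BASE / "association" / "association.tsv", sep="\t",
                        index_col=0)
    scores = io.read_scores(BASE / "pathways" / "ssgsva.tsv")
    sig = [p for p in assoc.index[assoc["significant"]]
           if p in scores.features]
    if len(sig) < 4:
        print(f"only {len(sig)} significant pathways; no factor model fitted")
        return
    sub = ScoreMatrix(scores.values.loc[sig], n_used=scores.n_used.loc[sig])
    reduced, groups = deduplicate_scores(sub, seed=7)
    fac = factorability(reduced)
    print(f"{len(sig)} significant pathways, {len(reduced.features)} after "
          f"collapsing {sum(len(g) for g in groups.values())} duplicates "
          f"into {len(groups)} groups")
    print(f"KMO = {fac['kmo']:.3f}; Bartlett chi2 = {fac['bartlett_chi2']:.1f} "
          f"(df {fac['bartlett_df']}, P = {fac['bartlett_p']:.3g})")
    try:
        solution = efa_removal_loop(reduced)
    except NoAdmissibleModelError as exc:
        print(f"no admissible factor model: {exc}")
        return
    model = reattach_duplicates(fit_cfa(reduced, solution), groups)
    out = BASE / "sem"
    out.mkdir(parents=True, exist_ok=True)
    model.loadings.to_csv(out / "loadings.tsv", sep="\t", float_format="%.10g")
    model.phi.to_csv(out / "factor_correlations.tsv", sep="\t",
                     float_format="%.10g")
    model.mod_indices.to_csv(out / "modification_indices.tsv", sep="\t",
                             index=False, float_format="%.10g")
    edge_list(model).to_csv(out / "edges.tsv", sep="\t", index=False,
                            float_format="%.10g")
    n_t2 = int((model.loadings["t"].dropna() > 2).sum())
    print(f"{solution.n_factors} factors over {len(solution.assignment)} "
          f"pathways; F_ML = {model.f_ml:.4f} "
          f"(chi2 = {model.chi2:.1f}); {n_t2} loadings with t > 2")
    print(f"removed during EFA: {len(solution.removed)} variables")


if __name__ == "__main__":
    main()
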