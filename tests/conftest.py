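import numpy as np
import pandas as pd
import pytest

from pathrisk.containers import DosageMatrix
from pathrisk.simulate import SimConfig, simulate_all


@pytest.fixture(scope="session")
def small_bundle():
    """One modest synthetic world shared by read-only tests."""
    cfg = SimConfig(n_individuals=80, n_variants=500, n_genes=120,
                    n_gene_sets=30, n_causal_variants=25,
                    planted_set_fraction=0.1, factor_block_sizes=(4, 4),
                    seed=11)
    return simulate_all(cfg, flip_fraction=0.1)


@pytest.fixture()
def qc_fixture():
    """Seven variants, 12 individuals; one variant fails each QC filter.

    Expected (hand enumeration, thresholds t_geno=0.15, t_mind=0.3,
    t_maf=0.05, t_hwe=1e-3):
      v_miss : 3/12 = 25% missing            -> variant missingness
      ind12  : missing at v_rare and v_hwe, 2/6 = 33% after v_miss drops
                                             -> individual missingness
      v_rare : monomorphic (all hom-ref)     -> MAF
      v_hwe  : 5 hom-ref / 6 hom-alt / 0 het -> HWE exact (p << 1e-3)
      v_ambig: A/T alleles                   -> strand-ambiguous
      v_dup2 : same id as v_dup1             -> duplicate id
      v_dup1, v_clean survive.
    """
    n = 12
    rng = np.random.default_rng(5)
    inds = [f"s{i:02d}" for i in range(n)]

    def het_balanced():
        # roughly HWE at MAF 0.5: 3/6/3
        return np.array([0, 0, 0, 1, 1, 1, 1, 1, 1, 2, 2, 2], float)

    cols = {
        "v_miss": het_balanced(),
        "v_rare": np.zeros(n),
        "v_hwe": np.array([0, 0, 0, 0, 0, 2, 2, 2, 2, 2, 2, 0], float),
        "v_ambig": het_balanced(),
        "v_dup": het_balanced(),
        "v_dup2": het_balanced(),
        "v_clean": het_balanced(),
    }
    ids = ["v_miss", "v_rare", "v_hwe", "v_ambig", "v_dup", "v_dup", "v_clean"]
    dosages = np.column_stack(list(cols.values()))
    missing = np.zeros(dosages.shape, bool)
    missing[0:3, 0] = True                   # v_miss: 25% missing
    missing[11, 1] = True                    # ind s11 missing at v_rare
    missing[11, 2] = True                    # ... and at v_hwe -> 2/6 = 33%
    variants = pd.DataFrame({
        "id": ids,
        "chrom": "1",
        "pos": np.arange(1, 8) * 10,
        "ref": ["A", "A", "A", "A", "A", "A", "A"],
        "alt": ["C", "C", "C", "T", "C", "C", "G"],
    })
    return DosageMatrix(inds, variants, dosages, missing)
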