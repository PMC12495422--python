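"""Core in-memory containers shared across the pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["DosageMatrix", "ScoreMatrix", "GeneSetCollection"]

VARIANT_COLUMNS = ["id", "chrom", "pos", "ref", "alt"]


@dataclass
class DosageMatrix:
    """Effect-allele dosages for diploid biallelic SNPs.

    ``dosages[i, v]`` is the ALT-allele count (in [0, 2]) of individual i at
    variant v; ``missing`` masks entries whose genotype was not called.
    Variant metadata lives in ``variants`` (columns id, chrom, pos, ref,
    alt; pos is 1-based as in VCF).
    """

    individuals: list[str]
    variants: pd.DataFrame
    dosages: np.ndarray
    missing: np.ndarray = None

    def __post_init__(self):
        self.individuals = list(self.individuals)
        self.variants = self.variants.reset_index(drop=True)
        self.dosages = np.asarray(self.dosages, dtype=np.float64)
        if self.missing is None:
            self.missing = np.zeros(self.dosages.shape, dtype=bool)
        self.missing = np.asarray(self.missing, dtype=bool)
        if list(self.variants.columns[:5]) != VARIANT_COLUMNS:
            raise ValueError(f"variant table must have columns {VARIANT_COLUMNS}")
        n_ind, n_var = self.dosages.shape
        if n_ind != len(self.individuals) or n_var != len(self.variants):
            raise ValueError("dosage matrix shape does not match metadata")
        if self.missing.shape != self.dosages.shape:
            raise ValueError("missing mask shape mismatch")
        if len(set(self.individuals)) != n_ind:
            raise ValueError("individual ids must be unique")
        if self.variants["id"].duplicated().any():
            # duplicated ids are allowed on input (QC removes them) but the
            # container flags them so lookups stay well defined
            self._has_dup_ids = True
        else:
            self._has_dup_ids = False
        if (self.variants["pos"] < 1).any():
            raise ValueError("positions must be 1-based (>= 1)")
        valid = self.dosages[~self.missing]
        if valid.size and (np.nanmin(valid) < 0 or np.nanmax(valid) > 2):
            raise ValueError("dosages must lie in [0, 2]")

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def allele_freq(self) -> np.ndarray:
        """Estimated ALT-allele frequency per variant (missing-aware)."""
        d = np.ma.masked_array(self.dosages, mask=self.missing)
        return np.asarray(d.mean(axis=0).filled(np.nan)) / 2.0

    def imputed_dosages(self) -> np.ndarray:
        """Dosages with missing entries replaced by the variant mean."""
        if not self.missing.any():
            return self.dosages.copy()
        d = np.ma.masked_array(self.dosages, mask=self.missing)
        means = d.mean(axis=0).filled(0.0)
        out = self.dosages.copy()
        idx = np.where(self.missing)
        out[idx] = means[idx[1]]
        return out

    def select_variants(self, mask) -> "DosageMatrix":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            cols = np.where(mask)[0]
        else:
            cols = mask
        return DosageMatrix(
            self.individuals,
            self.variants.iloc[cols],
            self.dosages[:, cols],
            self.missing[:, cols],
        )

    def select_individuals(self, mask) -> "DosageMatrix":
        mask = np.asarray(mask)
        rows = np.where(mask)[0] if mask.dtype == bool else mask
        return DosageMatrix(
            [self.individuals[i] for i in rows],
            self.variants,
            self.dosages[rows],
            self.missing[rows],
        )


@dataclass
class ScoreMatrix:
    """Genes-or-pathways x individuals real-valued matrix.

    Used both for predicted (genetically regulated) expression and for
    per-individual pathway scores.  ``n_used`` records, per row, how many
    underlying features (model variants / expressed member genes) went into
    the row.
    """

    values: pd.DataFrame
    n_used: pd.Series = None
    label: str = ""

    def __post_init__(self):
        if self.n_used is None:
            self.n_used = pd.Series(0, index=self.values.index)
        self.n_used = self.n_used.reindex(self.values.index)
        if self.values.index.duplicated().any():
            raise ValueError("row names must be unique")
        if not np.isfinite(self.values.to_numpy(float)).all():
            raise ValueError("scores must be finite (rows with no usable "
                             "features are omitted, not NaN-filled)")

    @property
    def features(self) -> list[str]:
        return list(self.values.index)

    @property
    def individuals(self) -> list[str]:
        return list(self.values.columns)

    def to_array(self) -> np.ndarray:
        return self.values.to_numpy(float)


class GeneSetCollection:
    """Named gene sets, GMT-compatible; names follow "type ~ ID ~ term"."""

    def __init__(self, sets: dict):
        clean = {}
        for name, members in sets.items():
            members = list(members)
            if not members:
                raise ValueError(f"gene set {name!r} has no members")
            if name in clean:
                raise ValueError(f"duplicate gene set name {name!r}")
            clean[name] = members
        self.sets = clean

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __getitem__(self, name):
        return self.sets[name]

    def items(self):
        return self.sets.items()

    def names(self) -> list[str]:
        return list(self.sets)

    def subset(self, names) -> "GeneSetCollection":
        return GeneSetCollection({n: self.sets[n] for n in names})
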