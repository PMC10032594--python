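"""Diploid STR unit-count genotype container and TSV round trip."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

MISSING = -1


@dataclass
class StrGenotypeMatrix:
    """Accessions x loci diploid unit-count calls.

    ``a1``/``a2`` are integer arrays of shape (n_accessions, n_loci) holding
    allele unit counts, with ``-1`` marking a missing call (both alleles of a
    call are missing together).
    """

    accessions: list[str]
    loci: list[str]
    a1: np.ndarray
    a2: np.ndarray

    def __post_init__(self) -> None:
        shape = (len(self.accessions), len(self.loci))
        if self.a1.shape != shape or self.a2.shape != shape:
            raise ValueError("allele arrays must be (n_accessions, n_loci)")
        if ((self.a1 == MISSING) != (self.a2 == MISSING)).any():
            raise ValueError("alleles of a call must be missing together")

    @property
    def n_accessions(self) -> int:
        return len(self.accessions)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def missing_mask(self) -> np.ndarray:
        return self.a1 == MISSING

    def diploid_sum(self) -> np.ndarray:
        """Continuous encoding: sum of the two allele unit counts (NaN if missing)."""
        out = (self.a1 + self.a2).astype(float)
        out[self.missing_mask()] = np.nan
        return out

    def to_long_df(self) -> pd.DataFrame:
        acc = np.repeat(self.accessions, self.n_loci)
        loc = np.tile(self.loci, self.n_accessions)
        return pd.DataFrame(
            {
                "accession": acc,
                "locus": loc,
                "allele1_units": self.a1.ravel(),
                "allele2_units": self.a2.ravel(),
            }
        )

    @classmethod
    def from_long_df(cls, df: pd.DataFrame) -> "StrGenotypeMatrix":
        accessions = sorted(df["accession"].unique())
        loci = sorted(df["locus"].unique())
        ai = {a: i for i, a in enumerate(accessions)}
        li = {l: j for j, l in enumerate(loci)}
        a1 = np.full((len(accessions), len(loci)), MISSING, dtype=int)
        a2 = np.full_like(a1, MISSING)
        rows = df["accession"].map(ai).to_numpy()
        cols = df["locus"].map(li).to_numpy()
        a1[rows, cols] = df["allele1_units"].to_numpy()
        a2[rows, cols] = df["allele2_units"].to_numpy()
        return cls(accessions, loci, a1, a2)

    def write_tsv(self, path) -> None:
        self.to_long_df().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path) -> "StrGenotypeMatrix":
        return cls.from_long_df(pd.read_csv(path, sep="\t"))
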