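"""Enrichment of STR-encoded residues in predicted regions via exact tests.

For an amino acid and a region track, the 2x2 table partitions the residue
universe into

=========  ==================  ======================
            in region           outside region
=========  ==================  ======================
STR         a                   c
non-STR     b                   d
=========  ==================  ======================

The odds ratio is the cross-ratio (a/b)/(c/d) = ad/bc and p-values come from
the exact hypergeometric distribution (Fisher's exact test), two-sided by
default with a one-sided (greater) variant available.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class ContingencyTable:
    a: int  # STR-encoded residues inside region
    b: int  # non-STR residues inside region
    c: int  # STR-encoded residues outside region
    d: int  # non-STR residues outside region

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def degenerate(self) -> bool:
        """A margin is empty: the test carries no information."""
        return (
            self.a + self.b == 0
            or self.c + self.d == 0
            or self.a + self.c == 0
            or self.b + self.d == 0
        )


@dataclass
class EnrichmentResult:
    amino_acid: str
    region: str
    log_odds: float
    p: float
    p_adjusted: float
    direction: str  # over / under / none


def build_contingency(
    tract_residues: set,
    region: set,
    universe: set,
    amino_acid: str | None = None,
) -> ContingencyTable:
    """Counts for the STR x region 2x2 table over a residue universe.

    ``tract_residues`` and ``region`` must be subsets of ``universe``; the
    four cells partition the universe exactly.
    """
    if not tract_residues <= universe:
        raise ValueError("tract residues must be a subset of the universe")
    if not region <= universe:
        raise ValueError("region residues must be a subset of the universe")
    a = len(tract_residues & region)
    b = len(region) - a
    c = len(tract_residues) - a
    d = len(universe) - a - b - c
    return ContingencyTable(a, b, c, d)


def fisher_exact(table: ContingencyTable, sided: str = "two") -> tuple[float, float]:
    """Odds ratio ad/bc and exact hypergeometric p for a 2x2 table.

    ``sided='two'`` sums probabilities of all tables with the same margins
    that are as or less probable than the observed one; ``sided='greater'``
    is the one-sided upper tail.  Zero cells give an odds ratio of 0 or +inf
    with a finite p; a fully degenerate table (empty margin) gives p = 1.
    """
    if sided not in {"two", "greater"}:
        raise ValueError("sided must be 'two' or 'greater'")
    a, b, c, d = table.a, table.b, table.c, table.d
    if b * c == 0:
        oddsr = math.inf if a * d > 0 else (0.0 if a * d == 0 and (b or c) else math.nan)
        if a * d == 0 and not (b or c):  # all mass in one cell or empty
            oddsr = math.nan
    else:
        oddsr = (a * d) / (b * c)
    if table.degenerate:
        return oddsr, 1.0
    alt = "two-sided" if sided == "two" else "greater"
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative=alt)
    return oddsr, float(p)


def bonferroni(pvals: Sequence[float], alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Bonferroni adjustment: min(1, p*m) with a strict significance flag."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    adj = np.minimum(1.0, p * p.size)
    return adj, adj < alpha


def enrichment_scan(
    tract_residues_by_aa: Mapping[str, set],
    regions: Mapping[str, set],
    universe: set,
    sided: str = "two",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """All (amino acid x region) Fisher tests with one Bonferroni family.

    Returns a tidy frame: amino_acid, region, a..d, odds_ratio, log_odds, p,
    p_adjusted, direction.  The correction family is every test run in this
    invocation.
    """
    rows = []
    for aa in sorted(tract_residues_by_aa):
        for reg in sorted(regions):
            tab = build_contingency(tract_residues_by_aa[aa], regions[reg], universe, aa)
            oddsr, p = fisher_exact(tab, sided=sided)
            rows.append(
                {
                    "amino_acid": aa,
                    "region": reg,
                    "a": tab.a,
                    "b": tab.b,
                    "c": tab.c,
                    "d": tab.d,
                    "odds_ratio": oddsr,
                    "log_odds": math.log(oddsr) if oddsr and math.isfinite(oddsr) and oddsr > 0 else (
                        -math.inf if oddsr == 0 else (math.inf if oddsr == math.inf else math.nan)
                    ),
                    "p": p,
                }
            )
    df = pd.DataFrame(rows)
    if df.empty:
        df["p_adjusted"] = []
        df["significant"] = []
        df["direction"] = []
        return df
    adj, sig = bonferroni(df["p"].to_numpy(), alpha=alpha)
    df["p_adjusted"] = adj
    df["significant"] = sig
    df["direction"] = np.where(
        ~sig, "none", np.where(df["odds_ratio"] > 1, "over", "under")
    )
    return df
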