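"""Meta-regression of association strength on tract features.

Which tract properties predict environmental signal?  For every locus the
association R^2 (best over axes), the maximum log10 Bayes factor and the
F_ST summary serve, in turn, as the response of a multiple linear regression
on the tract amino acid (one-hot against an alanine baseline), the ordinal
protein-binding agreement (0-3 PPI tools), and binary DNA-binding,
RNA-binding and disorder indicators.  Plain OLS t scores are reported with a
Bonferroni threshold recomputed from the actual coefficient count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

from strhab.tracts import TractFeatureVector

logger = logging.getLogger(__name__)


@dataclass
class MetaRegressionResult:
    response: str
    coefficients: pd.DataFrame  # index term; columns estimate, t, p, significant
    baseline_aa: str
    r2_model: float
    n: int
    alpha_bonferroni: float


def features_frame(features: Sequence[TractFeatureVector]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "locus": [f.locus_id for f in features],
            "amino_acid": [f.amino_acid for f in features],
            "in_disorder": [f.in_disorder for f in features],
            "protein_binding": [f.protein_binding for f in features],
            "dna_binding": [f.dna_binding for f in features],
            "rna_binding": [f.rna_binding for f in features],
        }
    )


def _clean_term(term: str, baseline: str) -> str:
    if term.startswith("C(amino_acid"):
        return "AA_" + term.split("[T.")[1].rstrip("]")
    return term


def fit_meta(
    features: pd.DataFrame | Sequence[TractFeatureVector],
    response: pd.Series,
    response_name: str,
    alpha: float = 0.05,
) -> MetaRegressionResult:
    """OLS of a per-locus response on tract features.

    ``features`` may be a frame (columns locus, amino_acid, in_disorder,
    protein_binding, dna_binding, rna_binding) or a sequence of
    :class:`TractFeatureVector`; ``response`` is indexed by locus.  The amino
    acid enters as a categorical against baseline alanine ('A'); if alanine is
    absent the lexicographically first code is used (logged).  The Bonferroni
    threshold is ``alpha`` divided by the number of non-intercept
    coefficients.
    """
    if not isinstance(features, pd.DataFrame):
        features = features_frame(features)
    df = features.set_index("locus").join(response.rename("resp"), how="inner")
    if len(df) < len(features):
        logger.warning("fit_meta: %d loci lack a response value", len(features) - len(df))
    if len(df) < 8:
        raise ValueError(f"insufficient loci for meta-regression (n={len(df)})")
    aas = sorted(df["amino_acid"].unique())
    if len(aas) < 2:
        raise ValueError("need at least 2 amino-acid classes")
    baseline = "A" if "A" in aas else aas[0]
    if baseline != "A":
        logger.info("fit_meta: alanine absent, baseline set to %r", baseline)
    formula = (
        f"resp ~ 1 + C(amino_acid, Treatment('{baseline}')) "
        "+ protein_binding + dna_binding + rna_binding + in_disorder"
    )
    # drop aliased (constant) terms up front so the design is full rank
    for col in ("protein_binding", "dna_binding", "rna_binding", "in_disorder"):
        if df[col].nunique() < 2:
            logger.warning("fit_meta: term %s constant, dropped", col)
            formula = formula.replace(f" + {col}", "")
    fit = smf.ols(formula, data=df).fit()
    with np.errstate(divide="ignore", invalid="ignore"):
        # a constant response has zero total sum of squares; define R^2 = 0
        r2 = fit.rsquared
    r2_model = float(r2) if np.isfinite(r2) else 0.0
    terms = [t for t in fit.params.index if t != "Intercept"]
    m = len(terms)
    alpha_b = alpha / m
    coef = pd.DataFrame(
        {
            "estimate": [fit.params[t] for t in terms],
            "t": [fit.tvalues[t] for t in terms],
            "p": [fit.pvalues[t] for t in terms],
        },
        index=[_clean_term(t, baseline) for t in terms],
    )
    coef["significant"] = coef["p"] < alpha_b
    return MetaRegressionResult(
        response=response_name,
        coefficients=coef,
        baseline_aa=baseline,
        r2_model=r2_model,
        n=int(len(df)),
        alpha_bonferroni=alpha_b,
    )


def run_all_meta(
    assoc_records: pd.DataFrame,
    bf_records: pd.DataFrame,
    fst_summary: pd.DataFrame,
    features: pd.DataFrame | Sequence[TractFeatureVector],
    selector: str = "min_p",
) -> dict[str, MetaRegressionResult]:
    """The three meta-regressions: responses r2, log10_bf and fst.

    Per-locus responses: association R^2 of the best test across axes
    (``selector='min_p'`` takes the record with the smallest p; ``'max_r2'``
    the largest R^2), maximum log10 Bayes factor across axes, and the
    per-locus F_ST summary.  Locus ids must join for >= 90% of tracts.
    """
    if not isinstance(features, pd.DataFrame):
        features = features_frame(features)
    assoc_records = assoc_records.reset_index(drop=True)
    if selector == "min_p":
        idx = assoc_records.groupby("locus")["p"].idxmin()
        r2 = assoc_records.loc[idx].set_index("locus")["r2"]
    elif selector == "max_r2":
        r2 = assoc_records.groupby("locus")["r2"].max()
    else:
        raise ValueError("selector must be 'min_p' or 'max_r2'")
    bf = bf_records.groupby("locus")["log10_bf"].max()
    fst = fst_summary.set_index("locus")["fst_mean"]

    loci = set(features["locus"])
    for name, resp in (("r2", r2), ("log10_bf", bf), ("fst", fst)):
        joined = len(loci & set(resp.index))
        if joined < 0.9 * len(loci):
            raise ValueError(
                f"misaligned inputs: only {joined}/{len(loci)} loci join for response {name}"
            )
    return {
        "r2": fit_meta(features, r2, "r2"),
        "log10_bf": fit_meta(features, bf, "log10_bf"),
        "fst": fit_meta(features, fst, "fst"),
    }
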