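"""Per-locus, per-axis genotype-environment association.

Each STR locus is tested against each environmental principal axis with the
axis as response.  Two genotype encodings are fitted: continuous (diploid
unit-count sum) and categorical (unordered allele-pair label, testing
nonlinear length effects).  For multiallelic loci the two models are compared
by a nested-model F-test and the better model's p and R^2 are kept; Bonferroni
correction runs over all (locus x axis) tests of a scan.  A mock scan
(per-locus shuffling of genotypes among accessions) provides the negative
control, and a kinship-corrected mixed model re-tests associations under
genetic structure.

The scans use closed-form least-squares arithmetic (group means / simple
regression) rather than a generic OLS routine; a unit test cross-checks the
results against statsmodels' OLS + anova_lm on the same data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from strhab.envspace import EnvPca
from strhab.genotypes import MISSING, StrGenotypeMatrix
from strhab.popgen import ld_prune

logger = logging.getLogger(__name__)

__all__ = [
    "StrGenotypeMatrix",
    "encode_locus",
    "ols_scan",
    "mock_scan",
    "MockScanResult",
    "kinship_from_snps",
    "lmm_scan",
]


# ---------------------------------------------------------------------------
# genotype encodings


def encode_locus(a1: np.ndarray, a2: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Continuous and categorical encodings for one locus.

    Returns ``(keep, cont, classes)`` where ``keep`` masks non-missing calls,
    ``cont`` is the diploid unit-count sum and ``classes`` integer-codes the
    unordered genotype labels {a,b} == {b,a}.  Singleton genotype classes are
    merged into the nearest class by unit-count-sum distance (ties toward the
    smaller class label) to prevent saturated categorical fits.
    """
    keep = a1 != MISSING
    lo = np.minimum(a1[keep], a2[keep])
    hi = np.maximum(a1[keep], a2[keep])
    cont = (lo + hi).astype(float)
    labels = [(int(l), int(h)) for l, h in zip(lo, hi)]
    uniq = sorted(set(labels))
    counts = {u: 0 for u in uniq}
    for lab in labels:
        counts[lab] += 1
    # iteratively merge singleton classes into the nearest surviving class
    merged: dict[tuple[int, int], tuple[int, int]] = {u: u for u in uniq}
    changed = True
    while changed and len(set(merged.values())) > 1:
        changed = False
        live = sorted(set(merged.values()))
        sizes = {u: 0 for u in live}
        for lab in labels:
            sizes[merged[lab]] += 1
        for u in live:
            if sizes[u] == 1 and len(live) > 1:
                others = [v for v in live if v != u]
                target = min(others, key=lambda v: (abs(sum(v) - sum(u)), v))
                for k, v in merged.items():
                    if v == u:
                        merged[k] = target
                changed = True
                break
    final = sorted(set(merged.values()))
    index = {u: i for i, u in enumerate(final)}
    classes = np.array([index[merged[lab]] for lab in labels])
    return keep, cont, classes


# ---------------------------------------------------------------------------
# OLS scan


def _linear_fit(g: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """R^2, model F p and SSE of y ~ 1 + g."""
    n = y.size
    gc = g - g.mean()
    yc = y - y.mean()
    sst = float(yc @ yc)
    sgg = float(gc @ gc)
    if sgg == 0 or sst == 0:
        return 0.0, 1.0, sst
    beta = float(gc @ yc) / sgg
    sse = sst - beta * float(gc @ yc)
    sse = max(sse, 0.0)
    r2 = 1 - sse / sst
    if sse == 0:
        return 1.0, 0.0, 0.0
    f = (sst - sse) / (sse / (n - 2))
    p = float(stats.f.sf(f, 1, n - 2))
    return r2, p, sse


def _categorical_fit(classes: np.ndarray, y: np.ndarray) -> tuple[float, float, float, int]:
    """R^2, model F p, SSE and class count of y ~ C(classes)."""
    n = y.size
    k = int(classes.max()) + 1
    sums = np.bincount(classes, weights=y, minlength=k)
    cnts = np.bincount(classes, minlength=k)
    means = sums / cnts
    resid = y - means[classes]
    sse = float(resid @ resid)
    yc = y - y.mean()
    sst = float(yc @ yc)
    if sst == 0:
        return 0.0, 1.0, sse, k
    r2 = 1 - sse / sst
    if n - k <= 0 or sse == 0:
        return r2, 0.0 if r2 > 0 else 1.0, sse, k
    f = ((sst - sse) / (k - 1)) / (sse / (n - k))
    p = float(stats.f.sf(f, k - 1, n - k))
    return r2, p, sse, k


def _nested_f_p(sse_lin: float, sse_cat: float, k: int, n: int) -> float:
    """p of the F-test comparing the categorical (k classes) to the linear model."""
    df1 = k - 2
    df2 = n - k
    if df1 <= 0 or df2 <= 0 or sse_cat <= 0:
        return 1.0
    f = ((sse_lin - sse_cat) / df1) / (sse_cat / df2)
    return float(stats.f.sf(max(f, 0.0), df1, df2))


def ols_scan(
    geno: StrGenotypeMatrix,
    axes: EnvPca | pd.DataFrame,
    alpha: float = 0.05,
    model_alpha: float = 0.05,
) -> pd.DataFrame:
    """Linear-vs-categorical OLS association of every locus with every axis.

    For biallelic loci (<= 2 genotype classes) the categorical and linear fits
    coincide and the model is recorded as ``linear``.  For multiallelic loci
    the categorical model is kept when the nested F-test favors it at
    ``model_alpha``.  The Bonferroni family is all retained (locus x axis)
    tests; ``bonferroni_significant`` uses the strict ``p_adj < alpha`` rule.
    Loci with fewer than two genotype classes are skipped with a log entry.
    """
    scores = axes.scores if isinstance(axes, EnvPca) else axes
    scores = scores.loc[geno.accessions]
    y_all = scores.to_numpy(dtype=float)
    axis_names = list(scores.columns)
    if np.any(y_all.std(axis=0) == 0):
        raise ValueError("constant environmental axis")
    rows = []
    for j, locus in enumerate(geno.loci):
        keep, cont, classes = encode_locus(geno.a1[:, j], geno.a2[:, j])
        k = int(classes.max()) + 1 if classes.size else 0
        n = int(keep.sum())
        if k < 2 or np.unique(cont).size < 2 or n < 4:
            logger.info("locus %s: <2 genotype classes, skipped", locus)
            continue
        n_alleles = len(np.unique(np.concatenate([
            geno.a1[keep, j] if keep.dtype == bool else geno.a1[:, j],
            geno.a2[keep, j] if keep.dtype == bool else geno.a2[:, j],
        ])))
        for a, axis in enumerate(axis_names):
            y = y_all[keep, a]
            r2_lin, p_lin, sse_lin = _linear_fit(cont, y)
            if k <= 2:
                rows.append(
                    {
                        "locus": locus,
                        "axis": axis,
                        "model": "linear",
                        "r2": r2_lin,
                        "p": p_lin,
                        "n_classes": k,
                        "n_alleles": n_alleles,
                        "n": n,
                    }
                )
                continue
            r2_cat, p_cat, sse_cat, _ = _categorical_fit(classes, y)
            p_nested = _nested_f_p(sse_lin, sse_cat, k, n)
            if p_nested < model_alpha:
                model, r2, p = "categorical", r2_cat, p_cat
            else:
                model, r2, p = "linear", r2_lin, p_lin
            rows.append(
                {
                    "locus": locus,
                    "axis": axis,
                    "model": model,
                    "r2": r2,
                    "p": p,
                    "n_classes": k,
                    "n_alleles": n_alleles,
                    "n": n,
                }
            )
    records = pd.DataFrame(rows)
    if records.empty:
        raise ValueError("no locus was testable")
    m = len(records)
    records["p_adj"] = np.minimum(1.0, records["p"] * m)
    records["bonferroni_significant"] = records["p_adj"] < alpha
    return records


def best_per_locus(records: pd.DataFrame) -> pd.DataFrame:
    """Top association (smallest p) per locus, with its axis retained."""
    idx = records.groupby("locus")["p"].idxmin()
    return records.loc[idx].reset_index(drop=True)


@dataclass
class MockScanResult:
    records: pd.DataFrame
    fraction_significant: float
    fraction_significant_best: float = field(default=float("nan"))


def mock_scan(
    geno: StrGenotypeMatrix,
    axes: EnvPca | pd.DataFrame,
    seed: int,
    alpha: float = 0.05,
    model_alpha: float = 0.05,
) -> MockScanResult:
    """Negative control: per-locus shuffling of genotypes among accessions.

    Genotype rows (both alleles together) are permuted independently per
    locus, destroying any genotype-environment relation while preserving the
    allele spectrum; the full OLS scan is then re-run.  Both tallies of the
    significant fraction are reported: over all (locus x axis) tests and over
    best-per-locus summaries.
    """
    rng = np.random.default_rng(seed)
    a1 = geno.a1.copy()
    a2 = geno.a2.copy()
    for j in range(geno.n_loci):
        perm = rng.permutation(geno.n_accessions)
        a1[:, j] = geno.a1[perm, j]
        a2[:, j] = geno.a2[perm, j]
    mock = StrGenotypeMatrix(geno.accessions, geno.loci, a1, a2)
    records = ols_scan(mock, axes, alpha=alpha, model_alpha=model_alpha)
    frac = float(records["bonferroni_significant"].mean())
    best = best_per_locus(records)
    frac_best = float(best["bonferroni_significant"].mean())
    return MockScanResult(records, frac, frac_best)


# ---------------------------------------------------------------------------
# kinship


def kinship_from_snps(
    snps: np.ndarray | pd.DataFrame,
    maf_max: float = 0.9,
    size: int = 1000,
    step: int = 20,
    threshold: float = 0.1,
) -> pd.DataFrame:
    """Standardized accession kinship from biallelic SNP dosages (0/1/2).

    SNPs with major-allele frequency >= ``maf_max`` are removed, the rest are
    LD-pruned (windowed greedy r^2 filter), and the pairwise Pearson
    correlation between accession dosage vectors is standardized to unit
    diagonal.
    """
    if isinstance(snps, pd.DataFrame):
        index = list(snps.index)
        X = snps.to_numpy(dtype=float)
    else:
        X = np.asarray(snps, dtype=float)
        index = [f"acc{i}" for i in range(X.shape[0])]
    freq = X.mean(axis=0) / 2
    major = np.maximum(freq, 1 - freq)
    X = X[:, major < maf_max]
    if X.shape[1] < 2:
        raise ValueError("fewer than 2 SNPs survive the frequency filter")
    kept = ld_prune(X, size=size, step=step, threshold=threshold)
    if kept.size < 2:
        raise ValueError("fewer than 2 SNPs survive LD pruning")
    # center each SNP by its mean dosage before correlating accessions, so
    # the shared allele-frequency profile does not swamp the structure signal
    Xc = X[:, kept] - X[:, kept].mean(axis=0)
    K = np.corrcoef(Xc)
    d = np.sqrt(np.clip(np.diag(K), 1e-12, None))
    K = K / np.outer(d, d)
    return pd.DataFrame(K, index=index, columns=index)


# ---------------------------------------------------------------------------
# linear mixed model


def _ml_loglik(yr: np.ndarray, Xr: np.ndarray, d: np.ndarray, delta: float) -> float:
    """Profile ML log-likelihood of the rotated model at variance ratio delta.

    Model: y = X b + u + e with cov = sigma_g^2 K + sigma_e^2 I and
    delta = sigma_e^2 / sigma_g^2; after rotation by K's eigenvectors the
    covariance is sigma_g^2 diag(d + delta).
    """
    n = yr.size
    w = 1.0 / (d + delta)
    Xw = Xr * w[:, None]
    xtx = Xr.T @ Xw
    beta = np.linalg.solve(xtx, Xw.T @ yr)
    r = yr - Xr @ beta
    s2 = float(np.sum(w * r * r)) / n
    s2 = max(s2, 1e-300)
    return -0.5 * (n * np.log(2 * np.pi * s2) + np.sum(np.log(d + delta)) + n)


def _ml_fit(yr: np.ndarray, Xr: np.ndarray, d: np.ndarray) -> float:
    """Max over delta (log-grid + golden refinement) of the profile ML log-likelihood."""
    from scipy.optimize import minimize_scalar

    res = minimize_scalar(
        lambda t: -_ml_loglik(yr, Xr, d, np.exp(t)),
        bounds=(-10.0, 10.0),
        method="bounded",
        options={"xatol": 1e-6},
    )
    return -float(res.fun)


def lmm_scan(
    geno: StrGenotypeMatrix,
    axes: EnvPca | pd.DataFrame,
    kinship: pd.DataFrame,
) -> pd.DataFrame:
    """Mixed-model re-test of every (locus, axis) with kinship random effects.

    Environment is the response; the continuous genotype encoding is the
    fixed effect of interest; the random effect has covariance
    sigma_g^2 K + sigma_e^2 I.  Variance components are estimated by maximum
    likelihood for both the null and genotype models so the likelihood-ratio
    statistic is coherent; p = chi2 survival at df = 1 (one genotype
    parameter added).  A single eigendecomposition of K is reused across all
    loci and axes.  A non-PSD kinship is projected to the nearest PSD matrix
    (eigenvalue clipping) with a warning.
    """
    scores = axes.scores if isinstance(axes, EnvPca) else axes
    scores = scores.loc[geno.accessions]
    K = kinship.loc[geno.accessions, geno.accessions].to_numpy()
    d, U = np.linalg.eigh((K + K.T) / 2)
    if d.min() < -1e-8:
        logger.warning("lmm_scan: kinship not PSD (min eig %.3g); clipping", d.min())
    d = np.clip(d, 0.0, None)
    y_rot = U.T @ scores.to_numpy(dtype=float)
    ones_rot = U.T @ np.ones(geno.n_accessions)
    rows = []
    for j, locus in enumerate(geno.loci):
        keep, cont, _ = encode_locus(geno.a1[:, j], geno.a2[:, j])
        if np.unique(cont).size < 2:
            continue
        if not keep.all():
            # missing calls: re-rotate on the subset (subset kinship)
            Ks = K[np.ix_(keep, keep)]
            ds, Us = np.linalg.eigh((Ks + Ks.T) / 2)
            ds = np.clip(ds, 0.0, None)
            y_sub = Us.T @ scores.to_numpy(dtype=float)[keep]
            one_sub = Us.T @ np.ones(int(keep.sum()))
            g_rot = Us.T @ cont
            d_use, y_use, one_use = ds, y_sub, one_sub
        else:
            g_rot = U.T @ cont
            d_use, y_use, one_use = d, y_rot, ones_rot
        X0 = one_use[:, None]
        X1 = np.column_stack([one_use, g_rot])
        for a, axis in enumerate(scores.columns):
            yr = y_use[:, a]
            ll0 = _ml_fit(yr, X0, d_use)
            ll1 = _ml_fit(yr, X1, d_use)
            lrt = max(0.0, 2 * (ll1 - ll0))
            p = float(stats.chi2.sf(lrt, df=1))
            rows.append({"locus": locus, "axis": axis, "lrt": lrt, "p_lmm": p})
    return pd.DataFrame(rows)
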