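"""Environmental variable space: scaling, PCA, retention rules, confound check.

Bioclimatic variables come in mixed units and are strongly intercorrelated;
association testing therefore runs against principal axes of the standardized
table.  Two retention rules are supported: the smallest prefix of axes
reaching a cumulative explained-variance target (e.g. 80%), and all axes each
explaining more than a per-axis minimum (e.g. 1%, used for subpopulation-mean
decompositions).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger(__name__)


@dataclass
class EnvPca:
    """Scores (accessions x axes), loadings (variables x axes), explained fractions."""

    scores: pd.DataFrame
    loadings: pd.DataFrame
    explained_fraction: np.ndarray
    retention_rule: str
    scaled: pd.DataFrame  # standardized input, kept for reconstruction checks

    @property
    def n_axes(self) -> int:
        return self.scores.shape[1]


def complete_case_filter(raw: pd.DataFrame) -> pd.DataFrame:
    """Keep only variables (columns) with zero missing values."""
    keep = raw.columns[raw.notna().all(axis=0)]
    dropped = raw.shape[1] - len(keep)
    if dropped:
        logger.info("complete_case_filter: dropped %d of %d variables", dropped, raw.shape[1])
    if len(keep) == 0:
        raise ValueError("all variables contain missing values")
    return raw[keep]


def _parse_rule(rule: str) -> tuple[str, float]:
    kind, _, val = rule.partition(":")
    if kind not in {"cumulative", "per_axis_min"} or not val:
        raise ValueError(f"unknown retention rule {rule!r}; use 'cumulative:0.8' or 'per_axis_min:0.01'")
    return kind, float(val)


def decompose(env: pd.DataFrame, rule: str = "cumulative:0.8", max_axes: int | None = None) -> EnvPca:
    """Standardize columns (population scaling) and decompose by SVD.

    Retention: ``cumulative:f`` keeps the smallest prefix of axes whose
    explained fractions sum to at least ``f``; ``per_axis_min:f`` keeps every
    axis individually explaining more than ``f``.  ``max_axes`` optionally
    caps the retained count.  The sign convention fixes each axis so the
    variable with the largest |loading| has a positive loading.  Zero-variance
    columns are dropped with a warning before scaling.
    """
    if env.shape[1] < 2:
        raise ValueError("need at least 2 variables")
    if env.shape[0] < 2:
        raise ValueError("need at least 2 rows")
    sd = env.std(axis=0, ddof=0)
    dead = sd.index[sd == 0]
    if len(dead):
        logger.warning("decompose: dropping %d zero-variance columns", len(dead))
        env = env.drop(columns=dead)
        sd = sd.drop(dead)
    scaled = (env - env.mean(axis=0)) / sd
    u, s, vt = np.linalg.svd(scaled.to_numpy(), full_matrices=False)
    frac = s**2 / np.sum(s**2)

    kind, val = _parse_rule(rule)
    if kind == "cumulative":
        k = int(np.searchsorted(np.cumsum(frac), val - 1e-12) + 1)
    else:
        k = int(np.sum(frac > val))
        k = max(k, 1)
    k = min(k, len(frac))
    if max_axes is not None:
        k = min(k, max_axes)

    scores = u[:, :k] * s[:k]
    loadings = vt[:k].T
    # sign convention: dominant variable per axis loads positively
    for j in range(k):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    axes = [f"PC{j + 1}" for j in range(k)]
    return EnvPca(
        scores=pd.DataFrame(scores, index=env.index, columns=axes),
        loadings=pd.DataFrame(loadings, index=env.columns, columns=axes),
        explained_fraction=frac[:k],
        retention_rule=rule,
        scaled=scaled,
    )


def subpop_mean_env(env: pd.DataFrame, subpops: pd.Series) -> pd.DataFrame:
    """Per-subpopulation mean of each variable (one row per subpopulation)."""
    missing = env.index.difference(subpops.index)
    if len(missing):
        raise ValueError(f"{len(missing)} accessions lack a subpopulation assignment")
    groups = env.groupby(subpops.loc[env.index])
    sizes = groups.size()
    if (sizes == 0).any():
        raise ValueError("empty subpopulation")
    return groups.mean()


def structure_envfit(kinship: pd.DataFrame, env_axes: EnvPca | pd.DataFrame) -> pd.DataFrame:
    """Regress each environmental axis on the top two kinship principal axes.

    The diagnostic for structure-environment confounding: a large R^2 means
    the environmental gradient is predictable from genetic structure alone.
    Returns a frame with axis, r2 and the F-test p-value.
    """
    K = kinship.to_numpy() if isinstance(kinship, pd.DataFrame) else np.asarray(kinship)
    if not np.allclose(K, K.T, atol=1e-8):
        raise ValueError("kinship must be symmetric")
    vals, vecs = np.linalg.eigh(K)
    pcs = vecs[:, ::-1][:, :2] * np.sqrt(np.clip(vals[::-1][:2], 0, None))
    X = sm.add_constant(pcs)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient structure design")
    scores = env_axes.scores if isinstance(env_axes, EnvPca) else env_axes
    rows = []
    for axis in scores.columns:
        fit = sm.OLS(scores[axis].to_numpy(), X).fit()
        rows.append({"axis": axis, "r2": fit.rsquared, "p": fit.f_pvalue})
    return pd.DataFrame(rows)
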