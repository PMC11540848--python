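"""Hidden-factor correction and inverse-normal transformation of traits.

Removes known covariates and data-driven latent factors (leading principal
components of the centered/scaled trait matrix) from each molecular trait,
then rank-transforms the residuals to a standard normal.  This realizes the
standard hidden-confounder cleanup applied to molecular phenotypes before QTL
mapping, with PCA factors chosen to capture a target fraction (default 99%)
of total variance.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .synthdata import TraitMatrix

logger = logging.getLogger(__name__)


@dataclass
class FactorConfig:
    """n_factors may be an int or "auto" (smallest K reaching variance_target)."""

    n_factors: int | str = "auto"
    variance_target: float = 0.99
    known_covariates: np.ndarray | None = None  # samples x covariates

    def __post_init__(self) -> None:
        if not (0.0 < self.variance_target <= 1.0):
            raise ValueError("variance_target must be in (0, 1]")
        if isinstance(self.n_factors, str) and self.n_factors != "auto":
            raise ValueError("n_factors must be a positive int or 'auto'")
        if isinstance(self.n_factors, int) and self.n_factors < 0:
            raise ValueError("n_factors must be nonnegative")


def _center_scale_impute(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-trait center/scale with missing values mean-imputed (to 0 after
    centering); constant traits are flagged for dropping."""
    x = values.copy()
    mean = np.nanmean(x, axis=1, keepdims=True)
    sd = np.nanstd(x, axis=1, keepdims=True)
    keep = (sd[:, 0] > 0) & np.isfinite(sd[:, 0])
    x = (x - mean) / np.where(sd > 0, sd, 1.0)
    x[np.isnan(x)] = 0.0
    return x, keep


def estimate_factors(traits: TraitMatrix, cfg: FactorConfig) -> np.ndarray:
    """Leading principal-component sample scores of the trait matrix.

    Returns a samples x K matrix.  With ``n_factors="auto"``, K is the
    smallest number of components whose cumulative explained variance
    reaches ``variance_target``.
    """
    x, keep = _center_scale_impute(traits.values)
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} constant trait rows before PCA")
        x = x[keep]
    n_traits, n_samples = x.shape
    if isinstance(cfg.n_factors, int) and n_samples < cfg.n_factors + 2:
        raise ValueError("n_samples must exceed n_factors + 1")

    # PCA over samples: SVD of the samples x traits matrix
    u, s, _ = np.linalg.svd(x.T, full_matrices=False)
    evr = (s**2) / (s**2).sum()
    if cfg.n_factors == "auto":
        k = int(np.searchsorted(np.cumsum(evr), cfg.variance_target) + 1)
        k = min(k, len(s))
    else:
        k = min(int(cfg.n_factors), len(s))
    logger.info("estimated %d PCA factors (explained variance %.4f)", k, float(np.cumsum(evr)[k - 1]))
    return u[:, :k] * s[:k]


def explained_variance_ratio(traits: TraitMatrix) -> np.ndarray:
    """Per-component explained variance of the centered/scaled trait matrix."""
    x, keep = _center_scale_impute(traits.values)
    s = np.linalg.svd(x[keep], compute_uv=False)
    return (s**2) / (s**2).sum()


def residualize(
    traits: TraitMatrix,
    factors: np.ndarray | None = None,
    known_covariates: np.ndarray | None = None,
) -> TraitMatrix:
    """Per-trait OLS residuals against [intercept | covariates | factors].

    Collinear design columns are dropped (with a warning) via a rank check.
    Missing trait values remain missing; the fit uses observed entries only.
    With no factors or covariates the output is simply the centered input.
    """
    n = len(traits.samples)
    cols = [np.ones((n, 1))]
    if known_covariates is not None and np.size(known_covariates):
        kc = np.atleast_2d(np.asarray(known_covariates, float))
        if kc.shape[0] != n:
            kc = kc.T
        cols.append(kc)
    if factors is not None and np.size(factors):
        cols.append(np.atleast_2d(np.asarray(factors, float)))
    X = np.concatenate(cols, axis=1)

    # drop collinear columns, keeping the earliest of each dependent set
    q, r = np.linalg.qr(X)
    keep_cols = np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(np.diag(r)).max())
    if not keep_cols.all():
        warnings.warn(f"dropping {int((~keep_cols).sum())} collinear design columns")
        X = X[:, keep_cols]

    out = traits.values.copy()
    full_rows = ~np.isnan(traits.values).any(axis=1)
    if full_rows.any():
        y = traits.values[full_rows]
        beta, *_ = np.linalg.lstsq(X, y.T, rcond=None)
        out[full_rows] = y - (X @ beta).T
    for i in np.flatnonzero(~full_rows):
        y = traits.values[i]
        obs = ~np.isnan(y)
        beta, *_ = np.linalg.lstsq(X[obs], y[obs], rcond=None)
        out[i, obs] = y[obs] - X[obs] @ beta
    return TraitMatrix(out, traits.traits.copy(), list(traits.samples))


def inverse_normal_transform(traits: TraitMatrix, min_nonmissing: int = 10) -> TraitMatrix:
    """Rank-based transform to normality: value -> Phi^-1((rank - 0.5) / n).

    Ties receive the average rank.  Traits with fewer than ``min_nonmissing``
    observed values are excluded (logged).  Output traits have mean ~= 0 and
    variance ~= 1 and depend on the input only through its ranks.
    """
    vals = traits.values
    keep = (~np.isnan(vals)).sum(axis=1) >= min_nonmissing
    if not keep.all():
        logger.info("excluding %d traits with < %d observed values", int((~keep).sum()), min_nonmissing)
    out = np.full((int(keep.sum()), vals.shape[1]), np.nan)
    for k, i in enumerate(np.flatnonzero(keep)):
        y = vals[i]
        obs = ~np.isnan(y)
        ranks = stats.rankdata(y[obs], method="average")
        out[k, obs] = stats.norm.ppf((ranks - 0.5) / obs.sum())
    return TraitMatrix(out, traits.traits.loc[keep].reset_index(drop=True), list(traits.samples))


def correct(traits: TraitMatrix, cfg: FactorConfig | None = None) -> TraitMatrix:
    """Convenience chain: estimate factors, residualize, inverse-normal."""
    cfg = cfg or FactorConfig()
    factors = estimate_factors(traits, cfg) if cfg.n_factors != 0 else None
    resid = residualize(traits, factors, cfg.known_covariates)
    return inverse_normal_transform(resid)
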