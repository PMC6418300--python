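"""Phenotypic preliminaries: scale reliability, Horn parallel analysis, and
single-factor maximum-likelihood factor analysis.

These statistics describe the items before any biometric modelling. They use
listwise deletion (near-complete item data is the expected regime here);
full-information handling of missingness is reserved for the twin models.
To respect the non-independence of co-twins, callers should pass one twin
per pair (see :func:`one_per_pair`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from statsmodels.multivariate.factor import Factor

from .data import TwinDataset

logger = logging.getLogger(__name__)


def one_per_pair(data: TwinDataset, seed: int = 0) -> np.ndarray:
    """(n_pairs, p) item matrix with one randomly selected twin per pair."""
    rng = np.random.default_rng(seed)
    y = data.phenotypes()
    p = data.p
    pick2 = rng.random(y.shape[0]) < 0.5
    out = np.where(pick2[:, None], y[:, p:], y[:, :p])
    # fall back to the co-twin when the chosen one is entirely missing
    empty = np.isnan(out).all(axis=1)
    alt = np.where(pick2[:, None], y[:, :p], y[:, p:])
    out[empty] = alt[empty]
    return out


def _complete_rows(items: np.ndarray) -> np.ndarray:
    items = np.asarray(items, dtype=float)
    keep = ~np.isnan(items).any(axis=1)
    return items[keep]


def cronbach_alpha(items: np.ndarray) -> float:
    """alpha = p/(p-1) * (1 - sum of item variances / variance of the sum)."""
    x = _complete_rows(items)
    n, p = x.shape
    if p < 2:
        raise ValueError("Cronbach's alpha requires at least 2 items")
    total_var = float(np.var(x.sum(axis=1), ddof=1))
    if total_var <= 0:
        raise ValueError("zero total-score variance; alpha undefined")
    item_var = float(np.var(x, axis=0, ddof=1).sum())
    return p / (p - 1.0) * (1.0 - item_var / total_var)


@dataclass
class ParallelAnalysisResult:
    """Observed, mean-random and adjusted correlation-matrix eigenvalues.

    ``adjusted = observed - random_mean + 1`` (the reported convention: an
    adjusted eigenvalue above 1 sits above the chance expectation for its
    rank). Retention counts observed eigenvalues exceeding the *retention
    threshold* for their rank: by default the 95th percentile of the random
    eigenvalues, because the mean rule turns rank-1 retention on pure noise
    into a coin flip (the observed top eigenvalue fluctuates symmetrically
    around the random mean).
    """

    observed: np.ndarray
    random_mean: np.ndarray
    adjusted: np.ndarray
    n_retained: int
    n_reps: int
    seed: int
    retention: str = "percentile"


def parallel_analysis(items: np.ndarray, n_reps: int = 500, seed: int = 0,
                      retention: str = "percentile",
                      percentile: float = 0.95) -> ParallelAnalysisResult:
    """Horn's parallel analysis against simulated independent-normal data.

    Simulates ``n_reps`` datasets of the same shape, collects their
    correlation-matrix eigenvalues per rank, and reports observed eigenvalues
    adjusted by the mean chance eigenvalue. ``retention='percentile'``
    (default) retains ranks whose observed eigenvalue exceeds the given
    quantile of the random eigenvalues — the convention that keeps the
    false-retention rate on pure noise at the nominal level;
    ``retention='mean'`` uses the plain adjusted-eigenvalue > 1 rule.
    """
    x = _complete_rows(items)
    n, p = x.shape
    if n <= p:
        raise ValueError("parallel analysis needs more rows than items")
    if n_reps < 100:
        logger.warning("parallel analysis with n_reps=%d (< 100) is noisy", n_reps)
    if retention not in ("percentile", "mean"):
        raise ValueError("retention must be 'percentile' or 'mean'")
    obs = np.sort(np.linalg.eigvalsh(np.corrcoef(x, rowvar=False)))[::-1]
    rng = np.random.default_rng(seed)
    rand = np.empty((n_reps, p))
    for r in range(n_reps):
        z = rng.standard_normal((n, p))
        rand[r] = np.sort(np.linalg.eigvalsh(np.corrcoef(z, rowvar=False)))[::-1]
    rand_mean = rand.mean(axis=0)
    adjusted = obs - rand_mean + 1.0
    if retention == "percentile":
        threshold = np.quantile(rand, percentile, axis=0)
        passes = obs > threshold
    else:
        passes = adjusted > 1.0
    # sequential rule: retain leading factors up to the first failure
    n_retained = int(np.argmin(passes)) if not passes.all() else int(p)
    return ParallelAnalysisResult(
        observed=obs, random_mean=rand_mean, adjusted=adjusted,
        n_retained=n_retained, n_reps=n_reps, seed=seed, retention=retention)


def ml_factor_1(items: np.ndarray) -> tuple[np.ndarray, float, bool]:
    """Single-factor ML factor analysis on the correlation matrix.

    Returns ``(loadings, proportion_of_variance, heywood)``; loadings follow
    the positive-sum sign convention and the proportion is
    ``sum(loadings^2) / p``. A Heywood solution (communality >= 1) is flagged
    and the offending loading capped at 0.999.
    """
    x = _complete_rows(items)
    n, p = x.shape
    corr = np.corrcoef(x, rowvar=False)
    if np.min(np.linalg.eigvalsh(corr)) <= 0:
        raise ValueError("sample correlation matrix is not positive definite")
    res = Factor(corr=corr, n_factor=1, method="ml", nobs=n).fit()
    loadings = np.asarray(res.loadings).ravel()
    if loadings.sum() < 0:
        loadings = -loadings
    heywood = bool(np.any(np.abs(loadings) >= 1.0))
    if heywood:
        logger.warning("Heywood case: communality >= 1; capping loading")
        loadings = np.clip(loadings, -0.999, 0.999)
    proportion = float(np.sum(loadings ** 2) / p)
    return loadings, proportion, heywood
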