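"""Per-replicate two-sample Z statistics and multi-replicate aggregation.

A gene's Z in one replicate is the standardized case-control difference of
its burden score.  With R phenotype replicates drawn on fixed genotypes the
per-gene Z's are positively correlated across replicates; the mean Z-bar
then has variance (1 + (R-1)*rho)/R rather than 1/R.  ``standardize``
rescales Z-bar back to unit variance before shrinkage, and
``rescale_shrunken`` maps shrunken values back onto the effect (delta)
scale used by the prediction rules.

rho is estimated by a moment identity: under the exchangeable model
Z_ir = delta_i + eps_ir with unit-variance, pairwise-rho errors, the
expected across-replicate sample variance of any gene equals 1 - rho, so
rho_hat = 1 - mean_i s2_i, clipped to [0, 1] against sampling noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class GeneStats:
    mean_case: float
    mean_control: float
    pooled_sd: float
    c_n: float  # sqrt(1/n1 + 1/n2)
    degenerate: bool = False


def two_sample_z(scores, labels):
    """Z statistic for one gene in one replicate.

    Z = (mean_case - mean_control) / (pooled_sd * sqrt(1/n1 + 1/n2)), with
    the pooled unbiased variance (divisor n1 + n2 - 2).  Returns
    ``(GeneStats, z)``; z is NaN and the stats flagged degenerate when the
    pooled variance is zero.
    """
    x = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if x.shape != y.shape:
        raise ValueError("scores and labels must have the same length")
    n1 = int(y.sum())
    n2 = len(y) - n1
    if n1 == 0 or n2 == 0:
        raise ValueError("both classes must be non-empty")
    m1 = x[y == 1].mean()
    m2 = x[y == 0].mean()
    ss = ((x[y == 1] - m1) ** 2).sum() + ((x[y == 0] - m2) ** 2).sum()
    sd = np.sqrt(ss / (n1 + n2 - 2))
    c_n = np.sqrt(1.0 / n1 + 1.0 / n2)
    if sd == 0:
        return GeneStats(m1, m2, 0.0, c_n, degenerate=True), np.nan
    return GeneStats(m1, m2, float(sd), float(c_n)), float((m1 - m2) / (sd * c_n))


def z_matrix(X, Y):
    """Vectorized Z statistics: genes x replicates.

    X is (n, G) scores, Y is (n, R) binary phenotypes.  Returns
    ``(Z, degenerate)`` where ``degenerate`` marks genes whose pooled sd is
    zero in at least one replicate (their Z entries are NaN there).
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    n = X.shape[0]
    n1 = Y.sum(axis=0)  # (R,)
    n2 = n - n1
    if (n1 == 0).any() or (n2 == 0).any():
        raise ValueError("every replicate needs both cases and controls")
    sum_case = Y.T @ X                      # (R, G)
    m1 = sum_case / n1[:, None]
    m2 = ((1 - Y).T @ X) / n2[:, None]
    sum_sq = Y.T @ (X ** 2) + (1 - Y).T @ (X ** 2)  # total sum of squares (R, G)
    ss = sum_sq - n1[:, None] * m1 ** 2 - n2[:, None] * m2 ** 2
    var = np.maximum(ss, 0.0) / (n - 2)
    c_n = np.sqrt(1.0 / n1 + 1.0 / n2)      # (R,)
    with np.errstate(divide="ignore", invalid="ignore"):
        Z = (m1 - m2) / (np.sqrt(var) * c_n[:, None])
    degenerate = (var <= 0).any(axis=0)
    Z = Z.T  # (G, R)
    Z[degenerate] = np.nan
    return Z, degenerate


def aggregate_replicates(Z) -> np.ndarray:
    """Per-gene arithmetic mean of Z across replicates."""
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    return Z.mean(axis=1)


def estimate_rho(Z) -> float:
    """Moment estimator of the common inter-replicate correlation."""
    Z = np.asarray(Z, dtype=float)
    if Z.ndim != 2 or Z.shape[1] < 2:
        raise ValueError("rho not estimable from fewer than 2 replicates; "
                         "supply rho explicitly")
    if Z.shape[0] < 2:
        raise ValueError("rho estimation needs at least 2 genes")
    s2 = Z.var(axis=1, ddof=1)
    return float(np.clip(1.0 - s2.mean(), 0.0, 1.0))


def replicate_factor(rho: float, R: int) -> float:
    """sqrt of Var(Z-bar) under the exchangeable-correlation model."""
    if not 0.0 <= rho <= 1.0:
        raise ValueError("rho must lie in [0, 1]")
    if R < 1:
        raise ValueError("R must be >= 1")
    return float(np.sqrt((1.0 + (R - 1) * rho) / R))


def standardize(zbar, rho: float, R: int) -> np.ndarray:
    """Rescale Z-bar to unit variance: zstar = zbar / sqrt((1+(R-1)rho)/R)."""
    return np.asarray(zbar, dtype=float) / replicate_factor(rho, R)


def rescale_shrunken(shrunk_zstar, rho: float, R: int) -> np.ndarray:
    """Map shrunken zstar back to the delta (Z-bar) scale."""
    return np.asarray(shrunk_zstar, dtype=float) * replicate_factor(rho, R)
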