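"""Full-information maximum-likelihood deviance for 4-dimensional normal data.

Rows are grouped by missingness pattern once per dataset; each deviance
evaluation then does one small Cholesky per pattern plus vectorized quadratic
forms, which keeps optimizer iterations cheap.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.linalg import cholesky, solve_triangular

_LOG_2PI = math.log(2.0 * math.pi)


def split_patterns(y: np.ndarray) -> list[tuple[np.ndarray, np.ndarray]]:
    """Group rows of an (n, 4) NaN-masked array by missingness pattern.

    Returns a list of (observed-column-index array, dense sub-matrix) tuples.
    Rows with no observed entry contribute nothing and are skipped.
    """
    y = np.asarray(y, dtype=float)
    obs = ~np.isnan(y)
    # encode each pattern as a 4-bit integer
    codes = obs @ (1 << np.arange(4))
    out: list[tuple[np.ndarray, np.ndarray]] = []
    for code in np.unique(codes):
        if code == 0:
            continue
        rows = codes == code
        cols = np.flatnonzero((int(code) >> np.arange(4)) & 1)
        out.append((cols, np.ascontiguousarray(y[np.ix_(rows, cols)])))
    return out


def neg2ll(
    patterns: list[tuple[np.ndarray, np.ndarray]],
    mu: np.ndarray,
    sigma: np.ndarray,
) -> float:
    """-2 log-likelihood of the observed sub-vectors under N(mu, sigma).

    Returns +inf when any observed sub-covariance is not positive definite.
    """
    total = 0.0
    for cols, ysub in patterns:
        sub = sigma[np.ix_(cols, cols)]
        try:
            chol = cholesky(sub, lower=True, check_finite=False)
        except Exception:
            return math.inf
        logdet = 2.0 * float(np.sum(np.log(np.diag(chol))))
        resid = ysub - mu[cols]
        z = solve_triangular(chol, resid.T, lower=True, check_finite=False)
        n_i, k = ysub.shape
        total += n_i * (k * _LOG_2PI + logdet) + float(np.sum(z * z))
    return total


def complete_moments(y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sample mean and ML (1/n) covariance of a complete (n, 4) matrix."""
    ybar = y.mean(axis=0)
    resid = y - ybar
    return ybar, resid.T @ resid / y.shape[0]


def pairwise_moments(y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Available-case mean and pairwise-complete covariance (optimizer starts).

    The result need not be positive definite; callers repair it if needed.
    """
    mu = np.nanmean(y, axis=0)
    cov = np.empty((4, 4))
    for i in range(4):
        for j in range(i, 4):
            both = ~np.isnan(y[:, i]) & ~np.isnan(y[:, j])
            n = int(both.sum())
            if n >= 2:
                di = y[both, i] - np.nanmean(y[both, i])
                dj = y[both, j] - np.nanmean(y[both, j])
                cov[i, j] = cov[j, i] = float(di @ dj / n)
            else:
                cov[i, j] = cov[j, i] = 0.0 if i != j else 1.0
    return mu, cov


def nearest_pd(sigma: np.ndarray, min_eig: float = 1e-6) -> np.ndarray:
    """Clip eigenvalues so the matrix is safely positive definite."""
    vals, vecs = np.linalg.eigh((sigma + sigma.T) / 2.0)
    vals = np.maximum(vals, min_eig)
    return vecs @ np.diag(vals) @ vecs.T
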