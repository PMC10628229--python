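"""Densities, log-likelihood and responsibilities for unconstrained GMMs.

All density work is done in log space via Cholesky factorizations; covariance
matrices are never inverted explicitly.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import solve_triangular
from scipy.special import logsumexp

from .params import Dataset, DegenerateCovarianceError, GMMParams

__all__ = [
    "component_log_densities",
    "log_likelihood",
    "responsibilities",
    "hard_assign",
]

_LOG_2PI = np.log(2.0 * np.pi)


def _as_matrix(data) -> np.ndarray:
    if isinstance(data, Dataset):
        return data.X
    return np.atleast_2d(np.asarray(data, dtype=float))


def component_log_densities(data, params: GMMParams) -> np.ndarray:
    """Per-component Gaussian log-densities, shape (n, K).

    Raises :class:`DegenerateCovarianceError` if any covariance fails to
    factorize; singularity is signalled, never silently floored.
    """
    X = _as_matrix(data)
    n, p = X.shape
    if p != params.p:
        raise ValueError(f"data dimension {p} != model dimension {params.p}")
    C = params.cholesky_factors()
    out = np.empty((n, params.K))
    for k in range(params.K):
        Z = solve_triangular(C[k], (X - params.means[k]).T, lower=True)
        logdet_half = np.sum(np.log(np.diag(C[k])))
        out[:, k] = -0.5 * p * _LOG_2PI - logdet_half - 0.5 * np.sum(Z * Z, axis=0)
    return out


def _weighted_log_densities(data, params: GMMParams) -> np.ndarray:
    logw = np.full(params.K, -np.inf)
    pos = params.weights > 0
    logw[pos] = np.log(params.weights[pos])
    return component_log_densities(data, params) + logw


def log_likelihood(data, params: GMMParams) -> dict:
    """Observed-data log-likelihood; returns ``{"total": ..., "mean": ...}``.

    ``mean`` is the empirical expected log-likelihood (total / n).
    """
    lse = logsumexp(_weighted_log_densities(data, params), axis=1)
    total = float(np.sum(lse))
    return {"total": total, "mean": total / len(lse)}


def responsibilities(data, params: GMMParams) -> np.ndarray:
    """Posterior component membership probabilities, shape (n, K).

    Computed in log space; each row sums to 1.
    """
    A = _weighted_log_densities(data, params)
    A -= logsumexp(A, axis=1, keepdims=True)
    return np.exp(A)


def hard_assign(resp: np.ndarray) -> np.ndarray:
    """MAP labels from a responsibility matrix; ties go to the lowest index."""
    return np.argmax(np.asarray(resp), axis=1)
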