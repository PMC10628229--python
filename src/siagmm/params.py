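"""Parameter containers for unconstrained Gaussian mixture models.

Two equivalent representations are used throughout:

* :class:`GMMParams` — the natural (constrained) space: simplex weights,
  component means and symmetric positive-definite covariances.
* :class:`UnconstrainedParams` — a smooth, unconstrained chart used for
  gradient ascent: component weights as free log-proportions ``alpha``
  (mapped to the simplex by a softmax) and covariances as log-Cholesky
  factors ``L`` with free off-diagonal entries and log-parameterized
  diagonal, so that ``Sigma = C @ C.T`` with ``C = tril(L, -1) +
  diag(exp(diag(L)))`` is positive definite by construction.

The log-proportion gauge freedom (any constant added to all ``alpha``
leaves the weights unchanged) is fixed by the zero-mean convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "GMMParams",
    "UnconstrainedParams",
    "Dataset",
    "DegenerateCovarianceError",
    "to_unconstrained",
    "to_constrained",
    "pack",
    "unpack",
]

_WEIGHT_TOL = 1e-10
_SYM_TOL = 1e-10


class DegenerateCovarianceError(ValueError):
    """A component covariance is singular / not positive definite."""

    def __init__(self, component: int, detail: str = ""):
        self.component = component
        msg = f"covariance of component {component} is not positive definite"
        if detail:
            msg += f": {detail}"
        super().__init__(msg)


@dataclass
class GMMParams:
    """Weights, means and covariances of a K-component GMM in p dimensions.

    ``weights`` has shape (K,), ``means`` (K, p), ``covariances`` (K, p, p).
    """

    weights: np.ndarray
    means: np.ndarray
    covariances: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.means = np.atleast_2d(np.asarray(self.means, dtype=float))
        self.covariances = np.asarray(self.covariances, dtype=float)
        if self.covariances.ndim == 2:  # K=1 convenience
            self.covariances = self.covariances[None, :, :]

    @property
    def K(self) -> int:
        return len(self.weights)

    @property
    def p(self) -> int:
        return self.means.shape[1]

    def validate(self) -> "GMMParams":
        """Check simplex and SPD invariants; raise ``ValueError`` on failure."""
        if self.K < 1 or self.p < 1:
            raise ValueError("need K >= 1 and p >= 1")
        if self.means.shape != (self.K, self.p):
            raise ValueError(f"means shape {self.means.shape} != {(self.K, self.p)}")
        if self.covariances.shape != (self.K, self.p, self.p):
            raise ValueError("covariances shape mismatch")
        if np.any(self.weights < 0):
            raise ValueError("negative mixture weight")
        if abs(self.weights.sum() - 1.0) > _WEIGHT_TOL:
            raise ValueError(f"weights sum to {self.weights.sum()}, not 1")
        for k, S in enumerate(self.covariances):
            if np.max(np.abs(S - S.T)) > _SYM_TOL:
                raise DegenerateCovarianceError(k, "not symmetric")
            try:
                np.linalg.cholesky(S)
            except np.linalg.LinAlgError:
                raise DegenerateCovarianceError(k, "Cholesky factorization failed")
        return self

    def cholesky_factors(self) -> np.ndarray:
        """Lower Cholesky factor of each covariance, shape (K, p, p)."""
        out = np.empty_like(self.covariances)
        for k, S in enumerate(self.covariances):
            try:
                out[k] = np.linalg.cholesky(S)
            except np.linalg.LinAlgError:
                raise DegenerateCovarianceError(k, "Cholesky factorization failed")
        return out

    def permuted(self, order) -> "GMMParams":
        order = np.asarray(order)
        return GMMParams(self.weights[order], self.means[order], self.covariances[order])

    def copy(self) -> "GMMParams":
        return GMMParams(self.weights.copy(), self.means.copy(), self.covariances.copy())


@dataclass
class UnconstrainedParams:
    """Unconstrained chart: softmax log-proportions + log-Cholesky factors.

    ``alphas`` (K,), ``means`` (K, p), ``cov_factors`` (K, p, p) lower
    triangular with the diagonal holding the *log* of the Cholesky diagonal.
    """

    alphas: np.ndarray
    means: np.ndarray
    cov_factors: np.ndarray

    def __post_init__(self) -> None:
        self.alphas = np.asarray(self.alphas, dtype=float)
        self.means = np.atleast_2d(np.asarray(self.means, dtype=float))
        self.cov_factors = np.asarray(self.cov_factors, dtype=float)

    @property
    def K(self) -> int:
        return len(self.alphas)

    @property
    def p(self) -> int:
        return self.means.shape[1]


@dataclass
class Dataset:
    """n x p observation matrix with optional integer ground-truth labels."""

    X: np.ndarray
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        if not np.all(np.isfinite(self.X)):
            raise ValueError("data matrix contains non-finite values")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if len(self.labels) != self.n:
                raise ValueError("labels length does not match number of rows")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]


def to_unconstrained(params: GMMParams) -> UnconstrainedParams:
    """Map constrained parameters to the unconstrained chart.

    The alpha gauge is fixed by the zero-mean convention. Round trip through
    :func:`to_constrained` is the identity (up to floating point).
    """
    params.validate()
    alphas = np.log(np.clip(params.weights, 1e-300, None))
    alphas = alphas - alphas.mean()
    C = params.cholesky_factors()
    factors = np.tril(C, -1)
    idx = np.arange(params.p)
    factors[:, idx, idx] = np.log(C[:, idx, idx])
    return UnconstrainedParams(alphas, params.means.copy(), factors)


def to_constrained(u: UnconstrainedParams) -> GMMParams:
    """Map the unconstrained chart back to valid GMM parameters."""
    if not (
        np.all(np.isfinite(u.alphas))
        and np.all(np.isfinite(u.means))
        and np.all(np.isfinite(u.cov_factors))
    ):
        raise ValueError("non-finite entries in unconstrained parameters")
    a = u.alphas - u.alphas.max()
    w = np.exp(a)
    w /= w.sum()
    C = _factors_to_cholesky(u.cov_factors)
    covs = C @ np.swapaxes(C, -1, -2)
    # symmetrize away factorization round-off
    covs = 0.5 * (covs + np.swapaxes(covs, -1, -2))
    return GMMParams(w, u.means.copy(), covs)


def _factors_to_cholesky(cov_factors: np.ndarray) -> np.ndarray:
    """Exponentiate the log-diagonal of the stored factors -> Cholesky factor."""
    C = np.tril(cov_factors, -1)
    idx = np.arange(cov_factors.shape[-1])
    C[..., idx, idx] = np.exp(cov_factors[..., idx, idx])
    return C


def pack(u: UnconstrainedParams) -> np.ndarray:
    """Flatten to a single optimizer vector: [alphas, means, tril factors]."""
    K, p = u.K, u.p
    il = np.tril_indices(p)
    tril = u.cov_factors[:, il[0], il[1]]
    return np.concatenate([u.alphas, u.means.ravel(), tril.ravel()])


def unpack(x: np.ndarray, K: int, p: int) -> UnconstrainedParams:
    """Inverse of :func:`pack`."""
    n_tril = p * (p + 1) // 2
    alphas = x[:K]
    means = x[K : K + K * p].reshape(K, p)
    tril = x[K + K * p :].reshape(K, n_tril)
    factors = np.zeros((K, p, p))
    il = np.tril_indices(p)
    factors[:, il[0], il[1]] = tril
    return UnconstrainedParams(alphas.copy(), means, factors)
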