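"""Fitting unconstrained GMMs: K-Means init, EM, gradient ascent and SIA.

Three fitters share the :class:`FitResult` container:

* :func:`em_fit` — textbook EM on the unconstrained model (monotone ascent
  of the total log-likelihood; degeneracy is signalled, not repaired).
* :func:`adgd_fit` — full-batch adaptive gradient ascent of the (optionally
  KL-penalized) likelihood on the unconstrained parameterization, using the
  analytic gradients in :mod:`siagmm._objective`.
* :func:`sia_fit` — the two-step sequential initialization algorithm: an
  unpenalized Step-I fit, then for each penalty weight on a grid a penalized
  gradient-ascent Step-II fit warm-started at Step I, the final solution
  selected as the one with minimum MPKL (ties go to the smallest weight,
  i.e. the solution closest to Step I).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp
from sklearn.cluster import KMeans

from . import core
from ._objective import objective_and_grad
from .kl import PenaltyWeights, klf_klb, mpkl
from .params import (
    Dataset,
    DegenerateCovarianceError,
    GMMParams,
    pack,
    to_constrained,
    to_unconstrained,
    unpack,
)

__all__ = [
    "FitResult",
    "SIAResult",
    "kmeans_init",
    "random_init",
    "em_fit",
    "adgd_fit",
    "sia_fit",
]

DEFAULT_WEIGHT_GRID = (0.0, 0.25, 0.5, 1.0, 1.25)


@dataclass
class FitResult:
    """A fitted GMM plus the bookkeeping reported for each solution."""

    params: GMMParams
    labels: np.ndarray
    loglik_total: float
    loglik_mean: float
    objective_trace: np.ndarray
    klf: float
    klb: float
    mpkl: float
    n_iter: int
    converged: bool
    method: str
    n_obs: int
    weights_used: PenaltyWeights | None = None
    degenerate: bool = False
    message: str = ""


@dataclass
class SIAResult:
    """Step-I fit, the per-weight Step-II fits, and the MPKL-selected one."""

    step1: FitResult
    step2_by_weight: dict
    selected: FitResult
    weight_grid: tuple


def _finalize(params, data, trace, n_iter, converged, method,
              weights_used=None, degenerate=False, message="") -> FitResult:
    ll = core.log_likelihood(data, params)
    labels = core.hard_assign(core.responsibilities(data, params))
    if params.K >= 2:
        kl = klf_klb(params)
        m = mpkl(params)
    else:
        kl = {"KLF": float("nan"), "KLB": float("nan")}
        m = float("nan")
    return FitResult(
        params=params,
        labels=labels,
        loglik_total=ll["total"],
        loglik_mean=ll["mean"],
        objective_trace=np.asarray(trace, dtype=float),
        klf=kl["KLF"],
        klb=kl["KLB"],
        mpkl=m,
        n_iter=n_iter,
        converged=converged,
        method=method,
        n_obs=data.n if isinstance(data, Dataset) else len(np.atleast_2d(data)),
        weights_used=weights_used,
        degenerate=degenerate,
        message=message,
    )


def kmeans_init(
    data: Dataset,
    K: int,
    seed: int = 0,
    init: str = "k-means++",
    n_init: int = 10,
    max_retries: int = 5,
) -> GMMParams:
    """K-Means partition turned into GMM parameters.

    Weights are cluster fractions, means the centroids, covariances the
    within-cluster sample covariances (eigenvalue-floored to positive
    definite when a cluster is degenerate).  Deterministic given ``seed``.
    """
    X = data.X
    n, p = X.shape
    if n < K:
        raise ValueError(f"need n >= K, got n={n}, K={K}")
    for attempt in range(max_retries):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            km = KMeans(n_clusters=K, init=init, n_init=n_init,
                        random_state=seed + attempt).fit(X)
        counts = np.bincount(km.labels_, minlength=K)
        if np.all(counts > 0):
            break
    else:
        raise RuntimeError(f"K-Means produced an empty cluster {max_retries} times")
    weights = counts / n
    means = km.cluster_centers_.copy()
    scale = float(np.mean(np.var(X, axis=0))) or 1.0
    covs = np.empty((K, p, p))
    for k in range(K):
        Xk = X[km.labels_ == k]
        if len(Xk) > p:
            S = np.atleast_2d(np.cov(Xk, rowvar=False))
        else:
            S = np.zeros((p, p))
        covs[k] = _floor_spd(S, 1e-6 * scale)
    return GMMParams(weights, means, covs)


def random_init(data: Dataset, K: int, seed: int = 0) -> GMMParams:
    """Plain random initialization: K distinct data points as means, equal
    weights, and randomly shrunk copies of the global covariance.

    Used for multi-restart landscape exploration, where K-Means starts are
    too stable to expose the diversity of likelihood local maxima.
    """
    rng = np.random.default_rng(seed)
    X = data.X
    if len(X) < K:
        raise ValueError("need n >= K")
    idx = rng.choice(len(X), size=K, replace=False)
    S = np.atleast_2d(np.cov(X, rowvar=False))
    S = _floor_spd(S, 1e-8 * (np.trace(S) / X.shape[1] + 1e-300))
    covs = np.stack([S * rng.uniform(0.1, 1.0) for _ in range(K)])
    return GMMParams(np.full(K, 1.0 / K), X[idx].copy(), covs)


def _floor_spd(S: np.ndarray, floor: float) -> np.ndarray:
    """Symmetrize and floor eigenvalues so the matrix is safely SPD."""
    S = 0.5 * (S + S.T)
    vals, vecs = np.linalg.eigh(S)
    if vals[0] > floor:
        return S
    vals = np.maximum(vals, floor)
    return (vecs * vals) @ vecs.T


def em_fit(
    data: Dataset,
    init: GMMParams,
    tol: float = 1e-6,
    max_iter: int = 500,
    eig_floor: float | None = None,
) -> FitResult:
    """EM for an unconstrained GMM, started from ``init``.

    Stops when the total log-likelihood improves by less than ``tol``.
    A collapsing component (non-PD M-step covariance) ends the run with
    ``degenerate=True`` and the last valid parameters, so that spurious /
    degenerate behaviour stays observable.  ``eig_floor`` optionally clips
    covariance eigenvalues (off by default).
    """
    X = data.X
    n, p = X.shape
    params = init.copy()
    params.validate()
    trace: list[float] = []
    prev = None
    converged = False
    degenerate = False
    message = ""
    it = 0
    for it in range(1, max_iter + 1):
        A = core._weighted_log_densities(X, params)
        ll_i = logsumexp(A, axis=1)
        total = float(ll_i.sum())
        trace.append(total)
        if prev is not None and total - prev < tol:
            converged = True
            break
        prev = total
        r = np.exp(A - ll_i[:, None])
        Nk = r.sum(axis=0)
        if np.any(Nk < 1e-10):
            degenerate = True
            message = f"component {int(np.argmin(Nk))} lost all responsibility"
            break
        new_w = Nk / n
        new_means = (r.T @ X) / Nk[:, None]
        new_covs = np.empty_like(params.covariances)
        failed = None
        for k in range(params.K):
            diffs = X - new_means[k]
            S = (r[:, k, None] * diffs).T @ diffs / Nk[k]
            S = 0.5 * (S + S.T)
            if eig_floor is not None:
                S = _floor_spd(S, eig_floor)
            try:
                np.linalg.cholesky(S)
            except np.linalg.LinAlgError:
                failed = k
                break
            new_covs[k] = S
        if failed is not None:
            degenerate = True
            message = f"M-step covariance of component {failed} is not positive definite"
            break
        params = GMMParams(new_w, new_means, new_covs)
    return _finalize(params, data, trace, it, converged, "em",
                     degenerate=degenerate, message=message)


def adgd_fit(
    data: Dataset,
    init: GMMParams,
    w: PenaltyWeights = PenaltyWeights(0.0, 0.0),
    tol: float = 1e-7,
    max_iter: int = 5000,
    lr: float = 5e-2,
    scale: str = "total",
    conv_patience: int = 30,
    plateau_patience: int = 200,
    max_lr_decays: int = 6,
) -> FitResult:
    """Gradient ascent of M = L - w1*KLF - w2*KLB with analytic gradients.

    Full-batch Adam-style ascent on the unconstrained parameterization;
    converged when the relative objective change stays below ``tol`` for
    ``conv_patience`` consecutive iterations (a single small step is not
    treated as convergence — adaptive ascent can move slowly through flat
    regions), or at ``max_iter``.  The learning rate is halved after
    ``plateau_patience`` iterations without improvement.  Deterministic
    given data and ``init``.  The returned parameters are the best iterate
    seen, so the final objective is never below the objective at ``init``.
    """
    init.validate()
    K, p = init.K, init.p
    X = data.X
    x = pack(to_unconstrained(init))
    m_t = np.zeros_like(x)
    v_t = np.zeros_like(x)
    b1, b2, eps = 0.9, 0.999, 1e-8
    trace: list[float] = []
    best_M = -np.inf
    best_x = x.copy()
    last_M = None
    since_best = 0
    n_small = 0
    decays = 0
    reset_used = False
    converged = False
    degenerate = False
    message = ""
    step = lr
    it = 0
    for it in range(1, max_iter + 1):
        try:
            M, g, _ = objective_and_grad(x, X, K, p, w.w1, w.w2, scale=scale)
        except (FloatingPointError, np.linalg.LinAlgError) as e:
            if not reset_used:
                # one rescue: restart from the best point with a halved step
                reset_used = True
                x = best_x.copy()
                m_t[:] = 0.0
                v_t[:] = 0.0
                step *= 0.5
                continue
            degenerate = True
            message = f"non-finite objective/gradient: {e}"
            break
        trace.append(M)
        if M > best_M:
            best_M = M
            best_x = x.copy()
            since_best = 0
        else:
            since_best += 1
        if last_M is not None and abs(M - last_M) < tol * (1.0 + abs(last_M)):
            n_small += 1
            if n_small >= conv_patience:
                converged = True
                break
        else:
            n_small = 0
        last_M = M
        if since_best >= plateau_patience:
            step *= 0.5
            since_best = 0
            decays += 1
            if decays > max_lr_decays:
                break
        m_t = b1 * m_t + (1 - b1) * g
        v_t = b2 * v_t + (1 - b2) * g * g
        mhat = m_t / (1 - b1**it)
        vhat = v_t / (1 - b2**it)
        x = x + step * mhat / (np.sqrt(vhat) + eps)
    params = to_constrained(unpack(best_x, K, p))
    return _finalize(params, data, trace, it, converged, "adgd",
                     weights_used=w, degenerate=degenerate, message=message)


def sia_fit(
    data: Dataset,
    K: int,
    weight_grid=DEFAULT_WEIGHT_GRID,
    seed: int = 0,
    step1_method: str = "em",
    kmeans_opts: dict | None = None,
    em_opts: dict | None = None,
    gd_opts: dict | None = None,
) -> SIAResult:
    """Two-step penalized fit with MPKL-based penalty-weight selection.

    Step I fits an unpenalized GMM (EM by default, or gradient ascent when
    ``step1_method='adgd'``) from a K-Means initialization.  Step II runs,
    for each value w on ``weight_grid`` (with w1 = w2 = w), penalized
    gradient ascent warm-started at the Step-I parameters.  The returned
    ``selected`` fit minimizes MPKL over the grid; ties break toward the
    smallest weight.  A failing grid point is recorded as ``None`` without
    failing the whole run.
    """
    weight_grid = tuple(sorted(float(v) for v in weight_grid))
    if len(weight_grid) == 0 or weight_grid[0] < 0:
        raise ValueError("weight_grid must be non-empty and non-negative")
    em_opts = em_opts or {}
    gd_opts = gd_opts or {}
    kmeans_opts = kmeans_opts or {}
    init = kmeans_init(data, K, seed=seed, **kmeans_opts)
    if step1_method == "em":
        step1 = em_fit(data, init, **em_opts)
    elif step1_method == "adgd":
        step1 = adgd_fit(data, init, PenaltyWeights(0.0, 0.0), **gd_opts)
    else:
        raise ValueError("step1_method must be 'em' or 'adgd'")
    step1.method = "sia-step1-" + step1_method

    step2: dict[float, FitResult | None] = {}
    for wv in weight_grid:
        try:
            fit = adgd_fit(data, step1.params, PenaltyWeights(wv, wv), **gd_opts)
            fit.method = "sia"
            step2[wv] = fit
        except Exception as e:  # record the failed grid point, keep going
            warnings.warn(f"SIA step II failed at weight {wv}: {e}")
            step2[wv] = None

    selected = None
    if K >= 2:
        for wv in weight_grid:  # ascending: ties go to the smallest weight
            fit = step2[wv]
            if fit is None or not np.isfinite(fit.mpkl):
                continue
            if selected is None or fit.mpkl < selected.mpkl:
                selected = fit
    if selected is None:  # K == 1 or every grid point failed
        ok = [f for f in step2.values() if f is not None]
        selected = ok[0] if ok else step1
    return SIAResult(step1=step1, step2_by_weight=step2,
                     selected=selected, weight_grid=weight_grid)
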