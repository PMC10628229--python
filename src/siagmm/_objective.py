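"""Penalized-likelihood objective and its analytic gradient.

Everything is expressed on the unconstrained chart (softmax log-proportions
``alpha``, means, log-Cholesky covariance factors) so that plain gradient
ascent stays inside the valid parameter space.  The gradient of

    M(theta) = L(theta) - w1 * KLF(theta) - w2 * KLB(theta)

is assembled from textbook pieces:

* d L / d alpha_k          = N_k - n * pi_k             (N_k = sum_i r_ik)
* d L / d mu_k             = Sigma_k^-1 sum_i r_ik (x_i - mu_k)
* d L / d Sigma_k          = 0.5 (Sigma_k^-1 S_k Sigma_k^-1 - N_k Sigma_k^-1)
* d KL(a||b) / d mu_a      = -Sigma_b^-1 (mu_b - mu_a)   (and + for mu_b)
* d KL(a||b) / d Sigma_a   = 0.5 (Sigma_b^-1 - Sigma_a^-1)
* d KL(a||b) / d Sigma_b   = 0.5 (Sigma_b^-1 - Sigma_b^-1 Sigma_a Sigma_b^-1
                                  - Sigma_b^-1 m m' Sigma_b^-1)

Covariance gradients (symmetric matrices D) are chained onto the Cholesky
factor via dF/dC = 2 D C, masked to the lower triangle, with the diagonal
multiplied by C_jj for the log parameterization.  Correctness is pinned by
finite-difference tests.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import cho_solve, solve_triangular
from scipy.special import logsumexp

_LOG_2PI = np.log(2.0 * np.pi)


def objective_and_grad(
    x: np.ndarray,
    X: np.ndarray,
    K: int,
    p: int,
    w1: float,
    w2: float,
    scale: str = "total",
):
    """Return (M, grad M, info) at packed unconstrained parameters ``x``.

    ``info`` carries the total log-likelihood and the KLF/KLB values at the
    same point.  Raises ``FloatingPointError`` on non-finite intermediates.
    """
    n = X.shape[0]
    n_tril = p * (p + 1) // 2
    alphas = x[:K]
    means = x[K : K + K * p].reshape(K, p)
    tril_flat = x[K + K * p :].reshape(K, n_tril)
    il = np.tril_indices(p)
    idx = np.arange(p)

    C = np.zeros((K, p, p))
    C[:, il[0], il[1]] = tril_flat
    d_log = C[:, idx, idx].copy()  # log of Cholesky diagonal
    C[:, idx, idx] = np.exp(d_log)

    # --- responsibilities and likelihood ---------------------------------
    a = alphas - logsumexp(alphas)
    pi = np.exp(a)
    logN = np.empty((n, K))
    Sinv = np.empty((K, p, p))
    eye = np.eye(p)
    for k in range(K):
        Z = solve_triangular(C[k], (X - means[k]).T, lower=True)
        logN[:, k] = -0.5 * p * _LOG_2PI - d_log[k].sum() - 0.5 * np.sum(Z * Z, axis=0)
        Sinv[k] = cho_solve((C[k], True), eye)
    A = logN + a
    ll_i = logsumexp(A, axis=1)
    L_total = float(ll_i.sum())
    r = np.exp(A - ll_i[:, None])
    Nk = r.sum(axis=0)

    g_alpha = Nk - n * pi
    g_mu = np.empty((K, p))
    D = np.empty((K, p, p))  # symmetric covariance gradients
    for k in range(K):
        diffs = X - means[k]
        rw = r[:, k]
        g_mu[k] = Sinv[k] @ (rw @ diffs)
        S_k = (rw[:, None] * diffs).T @ diffs
        D[k] = 0.5 * (Sinv[k] @ S_k @ Sinv[k] - Nk[k] * Sinv[k])

    s = 1.0 if scale == "total" else 1.0 / n
    g_alpha *= s
    g_mu *= s
    D *= s

    # --- KL penalty ------------------------------------------------------
    klf = 0.0
    klb = 0.0
    if K >= 2:
        Sigma = C @ np.swapaxes(C, -1, -2)
        logdet = 2.0 * d_log.sum(axis=1)
        for b_ in range(K):
            for a_ in range(K):
                if a_ == b_:
                    continue
                w = w1 if a_ < b_ else w2
                m = means[b_] - means[a_]
                Sb_inv = Sinv[b_]
                Sbm = Sb_inv @ m
                tr_term = float(np.sum(Sb_inv * Sigma[a_]))
                kl = 0.5 * (logdet[b_] - logdet[a_] + tr_term - p + m @ Sbm)
                if a_ < b_:
                    klf += kl
                else:
                    klb += kl
                if w != 0.0:
                    g_mu[a_] += w * Sbm
                    g_mu[b_] -= w * Sbm
                    D[a_] -= w * 0.5 * (Sb_inv - Sinv[a_])
                    SbSaSb = Sb_inv @ Sigma[a_] @ Sb_inv
                    D[b_] -= w * 0.5 * (Sb_inv - SbSaSb - np.outer(Sbm, Sbm))

    M = s * L_total - w1 * klf - w2 * klb

    # --- chain covariance gradients onto log-Cholesky factors ------------
    G_C = 2.0 * D @ C
    G_C[:, idx, idx] *= C[:, idx, idx]  # log-diagonal parameterization
    g_tril = G_C[:, il[0], il[1]]

    grad = np.concatenate([g_alpha, g_mu.ravel(), g_tril.ravel()])
    if not (np.isfinite(M) and np.all(np.isfinite(grad))):
        raise FloatingPointError("non-finite objective or gradient")
    info = {"L_total": L_total, "KLF": klf, "KLB": klb}
    return M, grad, info
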