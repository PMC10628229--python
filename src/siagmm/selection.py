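"""Information criteria, MPKL-based choice of K, and AIC-range grouping."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fit import FitResult, em_fit, kmeans_init, sia_fit
from .params import Dataset

__all__ = ["SelectionReport", "n_free_params", "aic", "bic", "select_k", "group_by_aic"]


def n_free_params(K: int, p: int) -> int:
    """Free parameters of an unconstrained K-component p-dimensional GMM:
    (K-1) weights + K*p means + K*p(p+1)/2 covariance entries."""
    if K < 1 or p < 1:
        raise ValueError("need K >= 1 and p >= 1")
    return (K - 1) + K * p + K * p * (p + 1) // 2


def aic(fit: FitResult) -> float:
    """AIC = 2k - 2 * total log-likelihood."""
    k = n_free_params(fit.params.K, fit.params.p)
    return 2.0 * k - 2.0 * fit.loglik_total


def bic(fit: FitResult, n: int | None = None) -> float:
    """BIC = k*log n - 2 * total log-likelihood (n taken from the fit)."""
    k = n_free_params(fit.params.K, fit.params.p)
    n = fit.n_obs if n is None else n
    return k * np.log(n) - 2.0 * fit.loglik_total


@dataclass
class SelectionReport:
    """Per-K criteria table and the MPKL-minimizing choice of K."""

    table: pd.DataFrame
    chosen_k: int
    fits: dict


def select_k(
    data: Dataset,
    k_range,
    method: str = "sia",
    seed: int = 0,
    **fit_opts,
) -> SelectionReport:
    """Fit each K in ``k_range`` and choose the one minimizing MPKL.

    ``method`` is 'sia' (default) or 'em'; additional options are forwarded
    to the fitter.  A failing K is recorded and excluded with a warning.
    Ties break toward the smaller K.
    """
    import warnings

    rows = []
    fits: dict[int, FitResult] = {}
    for K in sorted(int(k) for k in k_range):
        if K < 2:
            raise ValueError("select_k scans K >= 2 (MPKL is undefined for K=1)")
        try:
            if method == "sia":
                fit = sia_fit(data, K, seed=seed, **fit_opts).selected
            elif method == "em":
                fit = em_fit(data, kmeans_init(data, K, seed=seed), **fit_opts)
            else:
                raise ValueError("method must be 'sia' or 'em'")
        except Exception as e:
            warnings.warn(f"fit failed for K={K}: {e}")
            continue
        fits[K] = fit
        rows.append(
            {
                "K": K,
                "loglik": fit.loglik_total,
                "AIC": aic(fit),
                "BIC": bic(fit),
                "KLF": fit.klf,
                "KLB": fit.klb,
                "MPKL": fit.mpkl,
            }
        )
    if not rows:
        raise RuntimeError("every K in the range failed to fit")
    table = pd.DataFrame(rows)
    ok = table.dropna(subset=["MPKL"])
    chosen = int(ok.loc[ok["MPKL"].idxmin(), "K"])
    return SelectionReport(table=table, chosen_k=chosen, fits=fits)


def group_by_aic(
    fits,
    ranges,
    true_labels=None,
) -> pd.DataFrame:
    """Summarize a multi-restart solution set by AIC range.

    ``ranges`` is a list of (low, high) AIC intervals (inclusive).  For each
    group: solution count, mean/SD of AIC, mean/SD of ARI when ground-truth
    labels are given, mean weights and mean covariance determinants
    (components sorted by determinant for cross-restart comparability).
    """
    from .metrics import ari as _ari

    fits = list(fits)
    if not fits:
        raise ValueError("need at least one fit")
    aics = np.array([aic(f) for f in fits])
    rows = []
    for lo, hi in ranges:
        members = [f for f, a in zip(fits, aics) if lo <= a <= hi]
        row = {"aic_low": lo, "aic_high": hi, "count": len(members)}
        if members:
            a = np.array([aic(f) for f in members])
            row["aic_mean"] = a.mean()
            row["aic_sd"] = a.std(ddof=1) if len(a) > 1 else 0.0
            if true_labels is not None:
                r = np.array([_ari(true_labels, f.labels) for f in members])
                row["ari_mean"] = r.mean()
                row["ari_sd"] = r.std(ddof=1) if len(r) > 1 else 0.0
            K = members[0].params.K
            w = np.empty((len(members), K))
            d = np.empty((len(members), K))
            for i, f in enumerate(members):
                dets = np.linalg.det(f.params.covariances)
                order = np.argsort(dets)
                w[i] = f.params.weights[order]
                d[i] = dets[order]
            for k in range(K):
                row[f"weight_{k}"] = w[:, k].mean()
                row[f"det_{k}"] = d[:, k].mean()
        rows.append(row)
    return pd.DataFrame(rows)
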