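"""Clustering agreement metrics and the simulation benchmark runner."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score, rand_score

from .fit import adgd_fit, em_fit, kmeans_init, sia_fit
from .params import Dataset
from .simulate import SeparationConfig, UnbalancedConfig, cubed_random_cov, cubed_separation

__all__ = ["ari", "rand_index", "confusion", "run_benchmark"]

log = logging.getLogger(__name__)


def _check_pair(a, b):
    a = np.asarray(a).ravel()
    b = np.asarray(b).ravel()
    if len(a) != len(b):
        raise ValueError(f"label vectors differ in length: {len(a)} vs {len(b)}")
    if len(a) < 2:
        raise ValueError("need at least 2 points")
    return a, b


def ari(labels_a, labels_b) -> float:
    """Adjusted Rand index (pair-counting, chance-corrected, symmetric)."""
    a, b = _check_pair(labels_a, labels_b)
    return float(adjusted_rand_score(a, b))


def rand_index(labels_a, labels_b) -> float:
    """Unadjusted Rand index in [0, 1]."""
    a, b = _check_pair(labels_a, labels_b)
    return float(rand_score(a, b))


def confusion(labels_true, labels_pred) -> pd.DataFrame:
    """Contingency table with true classes as rows, predicted as columns."""
    t, p = _check_pair(labels_true, labels_pred)
    return pd.crosstab(
        pd.Series(t, name="true"), pd.Series(p, name="predicted")
    )


def _fit_one(data: Dataset, K: int, method: str, seed: int,
             em_opts=None, gd_opts=None, sia_opts=None):
    """One method on one dataset; returns predicted labels."""
    em_opts = em_opts or {}
    gd_opts = gd_opts or {}
    sia_opts = sia_opts or {}
    if method == "em":
        return em_fit(data, kmeans_init(data, K, seed=seed), **em_opts).labels
    if method == "adgd":
        return adgd_fit(data, kmeans_init(data, K, seed=seed), **gd_opts).labels
    if method == "sia":
        return sia_fit(data, K, seed=seed, em_opts=em_opts,
                       gd_opts=gd_opts, **sia_opts).selected.labels
    raise ValueError(f"unknown method {method!r}")


def run_benchmark(
    design: str,
    grid: dict,
    methods=("em", "adgd", "sia"),
    n_datasets: int = 50,
    seed: int = 0,
    em_opts: dict | None = None,
    gd_opts: dict | None = None,
    sia_opts: dict | None = None,
) -> pd.DataFrame:
    """Mean/SD ARI per (design cell, method) over seeded simulated datasets.

    ``design`` is 'separation' (grid keys: p, lam; K=3) or 'unbalanced'
    (grid keys: p, N2_per; K=2).  Every method sees the same datasets and
    the same K-Means initialization seed.  Per-dataset fit failures are
    excluded from the mean and counted in ``n_failed``.
    """
    if design == "separation":
        cells = [(p, lam) for p in grid["p"] for lam in grid["lam"]]
        cell_names = ("p", "lam")
        K = 3
    elif design == "unbalanced":
        cells = [(p, n2) for p in grid["p"] for n2 in grid["N2_per"]]
        cell_names = ("p", "N2_per")
        K = 2
    else:
        raise ValueError("design must be 'separation' or 'unbalanced'")

    master = np.random.SeedSequence(seed)
    rows = []
    for cell in cells:
        children = master.spawn(n_datasets)
        scores: dict[str, list] = {m: [] for m in methods}
        failures = {m: 0 for m in methods}
        for child in children:
            s = int(child.generate_state(1)[0] % (2**31))
            if design == "separation":
                data = cubed_separation(SeparationConfig(p=cell[0], lam=cell[1], seed=s))
            else:
                data = cubed_random_cov(UnbalancedConfig(p=cell[0], N2_per=cell[1], seed=s))
            for m in methods:
                try:
                    pred = _fit_one(data, K, m, seed=s, em_opts=em_opts,
                                    gd_opts=gd_opts, sia_opts=sia_opts)
                    scores[m].append(ari(data.labels, pred))
                except Exception as e:
                    failures[m] += 1
                    log.warning("fit failure (%s, cell %s): %s", m, cell, e)
        for m in methods:
            vals = np.array(scores[m])
            rows.append(
                {
                    "design": design,
                    cell_names[0]: cell[0],
                    cell_names[1]: cell[1],
                    "method": m,
                    "ari_mean": vals.mean() if len(vals) else np.nan,
                    "ari_sd": vals.std(ddof=1) if len(vals) > 1 else 0.0,
                    "n_datasets": len(vals),
                    "n_failed": failures[m],
                    "seed": seed,
                }
            )
    return pd.DataFrame(rows)
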