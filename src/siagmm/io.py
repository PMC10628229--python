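"""Delimited-text readers and JSON/CSV result writers."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .fit import FitResult, SIAResult
from .params import Dataset, GMMParams

__all__ = ["read_matrix", "read_labels", "write_result", "params_to_dict", "params_from_dict"]


def read_matrix(path, sep: str = ",", labels_path=None) -> Dataset:
    """Read an n x p numeric matrix from delimited text (header optional).

    A header row is auto-detected (first line with any non-numeric token).
    Raises a ``ValueError`` naming the offending row and column on a
    non-numeric cell.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep=sep, header=None, skipinitialspace=True)
    if raw.empty:
        raise ValueError(f"{path}: empty file")
    header = not np.all([_is_number(v) for v in raw.iloc[0]])
    if header:
        raw = raw.iloc[1:].reset_index(drop=True)
    X = np.empty(raw.shape, dtype=float)
    for j, col in enumerate(raw.columns):
        for i, v in enumerate(raw[col]):
            if not _is_number(v):
                row = i + (2 if header else 1)
                raise ValueError(f"{path}: non-numeric value {v!r} at row {row}, column {j + 1}")
            X[i, j] = float(v)
    labels = read_labels(labels_path) if labels_path else None
    return Dataset(X, labels)


def read_labels(path) -> np.ndarray:
    """Single integer column, one label per observation."""
    vals = pd.read_csv(path, header=None).iloc[:, 0]
    return vals.to_numpy(dtype=int)


def _is_number(v) -> bool:
    try:
        float(v)
        return True
    except (TypeError, ValueError):
        return False


def params_to_dict(params: GMMParams) -> dict:
    return {
        "weights": params.weights.tolist(),
        "means": params.means.tolist(),
        "covariances": params.covariances.tolist(),
    }


def params_from_dict(d: dict) -> GMMParams:
    return GMMParams(np.array(d["weights"]), np.array(d["means"]), np.array(d["covariances"]))


def _fit_to_dict(fit: FitResult) -> dict:
    from .selection import aic, bic

    return {
        "params": params_to_dict(fit.params),
        "loglik_total": fit.loglik_total,
        "loglik_mean": fit.loglik_mean,
        "AIC": aic(fit),
        "BIC": bic(fit),
        "KLF": fit.klf,
        "KLB": fit.klb,
        "MPKL": fit.mpkl,
        "n_iter": fit.n_iter,
        "converged": fit.converged,
        "degenerate": fit.degenerate,
        "method": fit.method,
        "weights_used": None
        if fit.weights_used is None
        else [fit.weights_used.w1, fit.weights_used.w2],
    }


def write_result(result, path, config: dict | None = None) -> list:
    """Write a fit (or SIA result, or DataFrame report) to disk.

    Parameters and criteria go to ``<path>.json`` (full precision); labels
    to ``<path>.labels.csv``; DataFrames to ``<path>.csv``.  The effective
    run configuration, when given, is echoed into the JSON for
    reproducibility.  Returns the list of files written.
    """
    path = Path(path)
    written = []
    if isinstance(result, pd.DataFrame):
        out = path.with_suffix(".csv")
        result.to_csv(out, index=False)
        return [out]
    if isinstance(result, SIAResult):
        payload = {
            "step1": _fit_to_dict(result.step1),
            "step2_by_weight": {
                str(w): None if f is None else _fit_to_dict(f)
                for w, f in result.step2_by_weight.items()
            },
            "selected": _fit_to_dict(result.selected),
            "weight_grid": list(result.weight_grid),
        }
        labels = result.selected.labels
    elif isinstance(result, FitResult):
        payload = _fit_to_dict(result)
        labels = result.labels
    else:
        raise TypeError(f"cannot serialize {type(result).__name__}")
    if config is not None:
        payload["config"] = config
    out = path.with_suffix(".json")
    out.write_text(json.dumps(payload, indent=2))
    written.append(out)
    lab_out = path.with_suffix(".labels.csv")
    pd.Series(labels).to_csv(lab_out, index=False, header=False)
    written.append(lab_out)
    return written
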