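"""Delete-d jackknife standard errors.

The estimator is recomputed on random subsets of the data with ``d``
observations deleted; with subset estimates theta_k (k = 1..m) and their
mean theta_bar, the standard error is

    SE = sqrt( (n - d) / (d * m) * sum_k (theta_k - theta_bar)^2 ).

Subsets are drawn without replacement within each draw and independently
across draws (seeded). The defaults — 50 subsets with 10 observations
deleted — match the resampling scheme used for the variance-component
heritability SEs.
"""

from __future__ import annotations

import math
from typing import Callable, Sequence

import numpy as np
import pandas as pd

__all__ = ["JackknifeError", "jackknife_se"]


class JackknifeError(RuntimeError):
    """The estimator failed on one of the jackknife subsets."""


def _take(data, idx: np.ndarray):
    if isinstance(data, pd.DataFrame) or isinstance(data, pd.Series):
        return data.iloc[idx]
    if isinstance(data, np.ndarray):
        return data[idx]
    return [data[i] for i in idx]


def jackknife_se(
    estimator: Callable[[object], float],
    data,
    n_subsets: int = 50,
    d: int = 10,
    seed: int | None = None,
    return_estimates: bool = False,
):
    """Delete-d jackknife SE of ``estimator`` over ``data`` of n units.

    ``data`` may be a sequence, ndarray, Series or DataFrame (rows are the
    resampling units). Deterministic given ``seed``. An estimator failure
    on a subset is re-raised as :class:`JackknifeError` naming the subset.
    """
    n = len(data)
    if d < 1:
        raise ValueError("d must be >= 1")
    if d >= n:
        raise ValueError(f"d = {d} must be smaller than the number of units n = {n}")
    if n_subsets < 2:
        raise ValueError("need at least 2 subsets")
    rng = np.random.default_rng(seed)
    estimates = np.empty(n_subsets)
    for k in range(n_subsets):
        keep = np.sort(rng.choice(n, size=n - d, replace=False))
        try:
            estimates[k] = float(estimator(_take(data, keep)))
        except Exception as exc:  # noqa: BLE001 - propagate with subset index
            raise JackknifeError(f"estimator failed on jackknife subset {k}: {exc}") from exc
    if np.ptp(estimates) == 0.0:
        se = 0.0  # constant estimator: exactly zero, no rounding residue
    else:
        se = math.sqrt(
            (n - d) / (d * n_subsets) * np.sum((estimates - estimates.mean()) ** 2)
        )
    if return_estimates:
        return se, estimates
    return se
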