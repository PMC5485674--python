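"""Goodness-of-fit statistics for simulated vs observed vectors.

The four statistics conventional in crop-model evaluation:

* ``r_squared`` -- squared Pearson correlation between simulated and
  observed values (scatter about the 1:1 line); a coefficient-of-
  determination variant (1 - SSE/SST) is available via ``r2_kind``.
* ``pct_rmse``  -- 100 * RMSE / mean(obs).
* ``pct_bias``  -- 100 * mean(sim - obs) / mean(obs) (signed).
* ``willmott_d`` -- Willmott's index of agreement,
  d = 1 - sum((sim-obs)^2) / sum((|sim - obar| + |obs - obar|)^2),
  in [0, 1] with 1 only for perfect agreement.

Both percentage statistics normalize by the observed mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import MetricError


@dataclass(frozen=True)
class EvalStats:
    r_squared: float
    pct_rmse: float
    pct_bias: float
    willmott_d: float
    n: int


def evaluate_predictions(sim, obs, r2_kind: str = "pearson") -> EvalStats:
    """Compute the four agreement statistics for paired vectors.

    Raises :class:`~beanphen.errors.MetricError` for fewer than two pairs
    or a zero observed mean.
    """
    sim = np.asarray(sim, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if sim.shape != obs.shape or sim.ndim != 1:
        raise MetricError("sim and obs must be equal-length 1-D vectors")
    n = len(obs)
    if n < 2:
        raise MetricError(f"need at least 2 pairs, got {n}")
    obar = obs.mean()
    if obar == 0.0:
        raise MetricError("observed mean is zero; % statistics undefined")

    err = sim - obs
    rmse = float(np.sqrt(np.mean(err**2)))
    pct_rmse = 100.0 * rmse / obar
    pct_bias = 100.0 * float(err.mean()) / obar

    denom = float(np.sum((np.abs(sim - obar) + np.abs(obs - obar)) ** 2))
    if denom == 0.0:
        willmott = 1.0 if np.allclose(sim, obs) else 0.0
    else:
        willmott = 1.0 - float(np.sum(err**2)) / denom

    if r2_kind == "pearson":
        if np.std(sim) == 0.0 or np.std(obs) == 0.0:
            r2 = float("nan")
        else:
            r2 = float(stats.pearsonr(sim, obs).statistic ** 2)
    elif r2_kind == "determination":
        sst = float(np.sum((obs - obar) ** 2))
        r2 = float("nan") if sst == 0.0 else 1.0 - float(np.sum(err**2)) / sst
    else:
        raise MetricError(f"unknown r2_kind {r2_kind!r}")

    return EvalStats(
        r_squared=r2,
        pct_rmse=pct_rmse,
        pct_bias=pct_bias,
        willmott_d=willmott,
        n=n,
    )
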