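"""Fit/prediction/generalisation criteria and model summary tables.

RMSE and MAE are in seconds; R^2 is ``1 - SS_res / SS_tot`` with the total sum
of squares taken about the observed mean of the same subset (negative values
are reported as-is).  The generalisation gap is evaluation RMSE minus training
RMSE: positive means the model fits its training window better than it
forecasts, i.e. overfits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["MetricSet", "compute_metrics", "summarize_models"]


@dataclass(frozen=True)
class MetricSet:
    rmse: float
    mae: float
    r2: float | None
    n: int
    scope: str  # train | valid | eval


def compute_metrics(y, yhat, scope: str = "eval") -> MetricSet:
    """Compute RMSE, MAE and R^2 of predictions against observations.

    R^2 is undefined (returned as None, with a warning) when the observations
    have zero variance but the residuals do not.
    """
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape or y.ndim != 1:
        raise ValueError("y and yhat must be equal-length one-dimensional arrays")
    if y.size < 1:
        raise ValueError("need at least one observation")
    resid = y - yhat
    ss_res = float(resid @ resid)
    rmse = float(np.sqrt(ss_res / y.size))
    mae = float(np.mean(np.abs(resid)))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        if ss_res == 0.0:
            r2 = 1.0
        else:
            warnings.warn("R^2 undefined: zero-variance observations with nonzero residuals")
            r2 = None
    else:
        r2 = 1.0 - ss_res / ss_tot
    return MetricSet(rmse=rmse, mae=mae, r2=r2, n=int(y.size), scope=scope)


def summarize_models(results: dict) -> pd.DataFrame:
    """Aggregate evaluation results into a Table-style summary.

    Parameters
    ----------
    results : mapping
        ``model label -> EvaluationResult`` (from :mod:`trainperf.tscv`).

    Returns
    -------
    DataFrame with one row per model: mean and sd of eval RMSE/MAE/R^2 across
    evaluation blocks, mean train RMSE, and the mean generalisation gap
    (eval RMSE - train RMSE).  Aggregation is over all completed blocks
    (pooled over athletes for individually fitted models).
    """
    if not results:
        raise ValueError("no results to summarise")
    rows = []
    for label, res in results.items():
        blocks = res.completed_blocks()
        if not blocks:
            rows.append({"model": label, "n_blocks": 0})
            continue
        ev_rmse = np.array([b["eval"].rmse for b in blocks])
        ev_mae = np.array([b["eval"].mae for b in blocks])
        ev_r2 = np.array([b["eval"].r2 for b in blocks if b["eval"].r2 is not None])
        gaps = np.array([b["eval"].rmse - b["train"].rmse for b in blocks])
        tr_rmse = np.array([b["train"].rmse for b in blocks])
        sd = lambda a: float(np.std(a, ddof=1)) if len(a) > 1 else 0.0
        rows.append(
            {
                "model": label,
                "n_blocks": len(blocks),
                "r2_mean": float(ev_r2.mean()) if len(ev_r2) else np.nan,
                "r2_sd": sd(ev_r2) if len(ev_r2) else np.nan,
                "mae_mean": float(ev_mae.mean()),
                "mae_sd": sd(ev_mae),
                "rmse_mean": float(ev_rmse.mean()),
                "rmse_sd": sd(ev_rmse),
                "train_rmse_mean": float(tr_rmse.mean()),
                "gap_mean": float(gaps.mean()),
                "gap_sd": sd(gaps),
            }
        )
    return pd.DataFrame(rows).set_index("model")
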