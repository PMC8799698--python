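"""Time-ordered model selection and rolling-forecasting-origin evaluation.

Observations are sorted by time and split into a selection set (the first 80%
by default) and an evaluation tail.  Hyper-parameters are chosen on the
selection set with expanding-window cross-validation: fold ``k`` trains on
everything before its validation block, a fixed-length block that immediately
follows the training window, and the candidate with the lowest mean
validation RMSE wins.  The chosen model is then evaluated on the held-out
tail one block at a time, refitting on all data strictly before each block —
the forecasting origin rolls forward through the tail.  No step ever uses an
observation from the future of the data it predicts.

For pooled (group) data the time ordering is by calendar day for all athletes
jointly, so no athlete's future can leak into another athlete's past.
The dose-response reference has no hyper-parameters and goes straight to the
evaluation phase.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from sklearn.base import BaseEstimator, clone

from .metrics import compute_metrics
from .models import EstimatorSpec, make_estimator

__all__ = [
    "FoldPlan",
    "SelectionResult",
    "EvaluationResult",
    "make_fold_plan",
    "select_model",
    "evaluate_model",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FoldPlan:
    """Deterministic time-ordered partition of the observations.

    All index arrays hold *positional* indices into the original data, already
    time-ordered.  ``folds`` pairs an expanding training window with the
    fixed-length validation block that follows it; ``eval_blocks`` tile the
    held-out tail.
    """

    n: int
    K: int
    valid_len: int
    eval_len: int
    order: np.ndarray
    selection: np.ndarray
    folds: tuple
    eval_blocks: tuple

    def describe(self) -> str:
        lines = [f"n={self.n} selection={len(self.selection)} K={self.K}"]
        for k, (tr, va) in enumerate(self.folds):
            lines.append(f"fold {k}: train {len(tr)} rows, valid rows {va[0]}..{va[-1]}")
        for b, blk in enumerate(self.eval_blocks):
            lines.append(f"eval block {b}: rows {blk[0]}..{blk[-1]}")
        return "\n".join(lines)


@dataclass
class SelectionResult:
    """Winning spec plus the full per-candidate per-fold RMSE table."""

    winner: EstimatorSpec
    scores: pd.DataFrame  # index: candidate label; columns: fold_k..., mean_rmse
    tie_note: str = ""


@dataclass
class EvaluationResult:
    """Per-evaluation-block train/eval metrics for one resolved model."""

    spec: EstimatorSpec
    blocks: list = field(default_factory=list)

    def completed_blocks(self):
        return [b for b in self.blocks if not b.get("failed")]

    @property
    def mean_eval_rmse(self) -> float:
        done = self.completed_blocks()
        if not done:
            return float("nan")
        return float(np.mean([b["eval"].rmse for b in done]))


def make_fold_plan(
    time_index,
    K: int = 5,
    eval_frac: float = 0.2,
    valid_len: int | None = None,
    eval_len: int | None = None,
) -> FoldPlan:
    """Plan the expanding-window folds and the rolling evaluation blocks.

    ``time_index`` is any sortable per-observation time key; ties keep input
    order (stable sort).  The evaluation tail holds ``ceil(eval_frac * n)``
    observations.  ``valid_len`` defaults to ``ceil(m / (K + 1))`` with ``m``
    the selection size; ``eval_len`` defaults to a third of the tail
    (rounded up), giving three rolling origins.  The final evaluation block
    may be shorter.
    """
    keys = np.asarray(time_index)
    n = len(keys)
    if n < 3:
        raise ValueError(f"need at least 3 observations, got {n}")
    if not 0.0 < eval_frac < 1.0:
        raise ValueError(f"eval_frac must lie in (0, 1), got {eval_frac}")
    order = np.argsort(keys, kind="stable")
    n_eval = math.ceil(eval_frac * n)
    m = n - n_eval
    if m < 2:
        raise ValueError(f"selection set too small ({m} rows) for eval_frac={eval_frac}")
    if valid_len is None:
        valid_len = math.ceil(m / (K + 1))
    if K < 1 or valid_len < 1:
        raise ValueError(f"K and valid_len must be >= 1, got K={K}, valid_len={valid_len}")
    if K * valid_len > m - 1:
        raise ValueError(
            f"infeasible plan: K*valid_len = {K * valid_len} leaves no training rows "
            f"(selection size {m}); reduce K or valid_len"
        )
    first_valid = m - K * valid_len
    folds = []
    for k in range(K):
        vs = first_valid + k * valid_len
        folds.append((order[:vs].copy(), order[vs : vs + valid_len].copy()))
    if eval_len is None:
        eval_len = math.ceil(n_eval / 3)
    if eval_len < 1:
        raise ValueError(f"eval_len must be >= 1, got {eval_len}")
    eval_blocks = tuple(
        order[s : min(s + eval_len, n)].copy() for s in range(m, n, eval_len)
    )
    return FoldPlan(
        n=n,
        K=K,
        valid_len=int(valid_len),
        eval_len=int(eval_len),
        order=order,
        selection=order[:m].copy(),
        folds=tuple(folds),
        eval_blocks=eval_blocks,
    )


def _predictor_columns(data: pd.DataFrame):
    return [c for c in data.columns if c.startswith("X")]


def _is_dr(spec) -> bool:
    from .dose_response import DoseResponseModel

    return (isinstance(spec, EstimatorSpec) and spec.family == "dr") or isinstance(
        spec, DoseResponseModel
    )


def _model_inputs(data: pd.DataFrame, spec) -> pd.DataFrame:
    if _is_dr(spec):
        return data[["athlete_id", "day"]]
    return data[_predictor_columns(data)]


def _factory(spec, loads, seed):
    """Estimator builder from either an EstimatorSpec or a prototype instance."""
    if isinstance(spec, BaseEstimator):
        return lambda: clone(spec)
    return lambda: make_estimator(spec, loads=loads, seed=seed)


def _spec_label(spec) -> str:
    return spec.label() if isinstance(spec, EstimatorSpec) else repr(spec)


def select_model(
    candidates,
    data: pd.DataFrame,
    plan: FoldPlan,
    loads=None,
    seed: int = 0,
) -> SelectionResult:
    """Choose the candidate with the lowest mean validation RMSE.

    Every candidate is fitted on each fold's expanding training window and
    scored on the validation block that follows it.  Candidates that fail on
    any fold are excluded (with the reason logged).  Exact ties on the mean
    are broken in favour of the more regularised candidate.
    """
    candidates = list(candidates)
    if not candidates:
        raise ValueError("no candidates supplied")
    y = data["y"].to_numpy(dtype=float)
    rows = {}
    usable = []
    for spec in candidates:
        X = _model_inputs(data, spec)
        build = _factory(spec, loads, seed)
        fold_rmse = []
        try:
            for tr, va in plan.folds:
                est = build()
                est.fit(X.iloc[tr], y[tr])
                fold_rmse.append(compute_metrics(y[va], est.predict(X.iloc[va]), "valid").rmse)
        except Exception as exc:  # candidate excluded, not fatal
            logger.warning("candidate %s excluded: %s", _spec_label(spec), exc)
            continue
        rows[_spec_label(spec)] = fold_rmse
        usable.append((spec, float(np.mean(fold_rmse))))
    if not usable:
        raise RuntimeError("all candidates failed during model selection")
    best_mean = min(u[1] for u in usable)
    tied = [u[0] for u in usable if u[1] == best_mean]
    winner = sorted(
        tied,
        key=lambda s: s.regularisation_key() if isinstance(s, EstimatorSpec) else (),
    )[0]
    tie_note = (
        f"{len(tied)} candidates tied at mean RMSE {best_mean:.6g}; "
        "most regularised preferred" if len(tied) > 1 else ""
    )
    scores = pd.DataFrame.from_dict(
        rows, orient="index", columns=[f"fold_{k}" for k in range(plan.K)]
    )
    scores["mean_rmse"] = scores.mean(axis=1)
    return SelectionResult(winner=winner, scores=scores, tie_note=tie_note)


def evaluate_model(
    spec: EstimatorSpec,
    data: pd.DataFrame,
    plan: FoldPlan,
    loads=None,
    seed: int = 0,
) -> EvaluationResult:
    """Rolling-forecasting-origin evaluation of a fully resolved model.

    For each evaluation block the model is refitted on *all* observations
    strictly before the block (the selection data plus earlier evaluation
    blocks) and scored on the block.  A refit failure marks the block failed
    and the run continues.
    """
    y = data["y"].to_numpy(dtype=float)
    X = _model_inputs(data, spec)
    build = _factory(spec, loads, seed)
    result = EvaluationResult(spec=spec)
    m = len(plan.selection)
    for b, block in enumerate(plan.eval_blocks):
        start = m + b * plan.eval_len
        train_pos = plan.order[:start]
        record = {"block": b, "n_train": len(train_pos), "n_eval": len(block)}
        try:
            est = build()
            est.fit(X.iloc[train_pos], y[train_pos])
            record["train"] = compute_metrics(
                y[train_pos], est.predict(X.iloc[train_pos]), "train"
            )
            record["eval"] = compute_metrics(y[block], est.predict(X.iloc[block]), "eval")
            record["failed"] = False
        except Exception as exc:
            logger.warning("block %d failed for %s: %s", b, _spec_label(spec), exc)
            record.update(failed=True, reason=str(exc))
        result.blocks.append(record)
    if any(b.get("failed") for b in result.blocks):
        logger.warning(
            "%s: %d/%d evaluation blocks failed",
            _spec_label(spec),
            sum(b.get("failed", False) for b in result.blocks),
            len(result.blocks),
        )
    return result
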