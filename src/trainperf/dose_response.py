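"""Variable dose-response (Busso) impulse-response model of performance.

The model maps a daily training-load series ``w(t)`` to performance (here a
time-trial time in seconds, lower is better) through two antagonistic
exponentially weighted sums — an aptitude (fitness) component with gain ``k1``
and time constant ``tau1``, and a fatigue component whose gain ``k2(t)`` is
itself a convolution of the load (gain ``k3``, time constant ``tau3``), making
fatigue dose-dependent::

    y_hat(t) = y* + k1 * sum_{l=1}^{t-1} w(l) exp(-(t-l)/tau1)
                  -      sum_{l=1}^{t-1} k2(l) w(l) exp(-(t-l)/tau2)
    k2(l)    = k3 * sum_{m=1}^{l} w(m) exp(-(l-m)/tau3)

Both sums stop at ``t - 1``: a session has no same-day effect on performance.
The five free parameters (k1, k3, tau1, tau2, tau3) are fitted by minimising
the residual sum of squares over performance days; the baseline ``y*`` is held
fixed (by default the athlete's first recorded performance) because optimising
the offset as well is known to overfit badly on the short series typical of
athlete monitoring.

Fitting uses variable projection: conditional on the three time constants the
model is linear in (k1, k3), so the gains are profiled out exactly by least
squares and a quasi-Newton search runs over log time constants only.  This
minimises the same RSS over all five parameters while sidestepping the severe
ill-conditioning of the raw parameterisation (k1 ~ 1e-5, k3 ~ 1e-9 on typical
load scales).  A small seeded multi-start guards against local minima.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from sklearn.base import BaseEstimator, RegressorMixin

logger = logging.getLogger(__name__)

__all__ = [
    "DRParams",
    "DRFit",
    "DEFAULT_TAU_BOUNDS",
    "k2_series",
    "predict_dr",
    "rss_dr",
    "fit_dr",
    "DoseResponseModel",
]

#: Default search bounds on the time constants, days: (tau1, tau2, tau3).
DEFAULT_TAU_BOUNDS = ((5.0, 80.0), (1.0, 60.0), (0.5, 30.0))

#: Typical starting values for the time constants, days.
_TAU_START = (36.0, 22.0, 5.0)


@dataclass(frozen=True)
class DRParams:
    """Parameters of the variable dose-response model.

    ``y_star`` is the basic level of performance in seconds; ``k1`` and ``k3``
    are gain terms (unconstrained in sign — with time-trial times, negative
    gains mean training lowers the time); ``tau1``/``tau2``/``tau3`` are the
    aptitude, fatigue and fatigue-gain time constants in days.
    """

    y_star: float
    k1: float
    k3: float
    tau1: float
    tau2: float
    tau3: float

    def __post_init__(self) -> None:
        for name in ("tau1", "tau2", "tau3"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")


@dataclass
class DRFit:
    """Result of fitting the dose-response model."""

    params: DRParams
    rss: float
    n_obs: int
    converged: bool
    n_starts_used: int
    start_rss: list = field(default_factory=list)
    at_bounds: bool = False


def _check_loads(w) -> np.ndarray:
    w = np.asarray(w, dtype=float)
    if w.ndim != 1:
        raise ValueError("loads must be a one-dimensional daily series")
    if not np.all(np.isfinite(w)):
        raise ValueError("loads contain non-finite values")
    return w


def _ewma_components(w: np.ndarray, tau1: float, tau2: float, tau3: float):
    """Aptitude and (unit-gain) fatigue sums on the full day grid 1..T.

    Returns arrays ``a`` and ``c`` with ``a[t-1] = sum_{l<t} w(l) e^{-(t-l)/tau1}``
    and ``c[t-1] = sum_{l<t} u(l) w(l) e^{-(t-l)/tau2}`` where
    ``u(l) = sum_{m<=l} w(m) e^{-(l-m)/tau3}`` (so k2 = k3 * u).  Computed by
    O(T) exponential recursions.
    """
    T = len(w)
    a = np.zeros(T)
    c = np.zeros(T)
    u = np.zeros(T)
    d3 = np.exp(-1.0 / tau3)
    acc = 0.0
    for l in range(T):  # u(l): includes the m = l term
        acc = w[l] + d3 * acc
        u[l] = acc
    d1 = np.exp(-1.0 / tau1)
    d2 = np.exp(-1.0 / tau2)
    acc_a = 0.0
    acc_c = 0.0
    for t in range(1, T):
        acc_a = d1 * (acc_a + w[t - 1])
        acc_c = d2 * (acc_c + u[t - 1] * w[t - 1])
        a[t] = acc_a
        c[t] = acc_c
    return a, c


def k2_series(w, k3: float, tau3: float):
    """Dose-dependent fatigue gain ``k2(l) = k3 * sum_{m<=l} w(m) e^{-(l-m)/tau3}``."""
    if not tau3 > 0:
        raise ValueError(f"tau3 must be > 0, got {tau3}")
    w = _check_loads(w)
    decay = np.exp(-1.0 / tau3)
    out = np.empty_like(w)
    acc = 0.0
    for l in range(len(w)):
        acc = w[l] + decay * acc
        out[l] = acc
    return k3 * out


def _check_days(days, T: int) -> np.ndarray:
    days = np.asarray(days, dtype=int)
    if days.ndim != 1:
        raise ValueError("days must be one-dimensional")
    if np.any(days < 1) or np.any(days > T):
        raise ValueError(f"requested days must lie in [1, {T}] (the load grid)")
    return days


def predict_dr(w, params: DRParams, days):
    """Model-predicted performance (seconds) on the requested days."""
    w = _check_loads(w)
    days = _check_days(days, len(w))
    a, c = _ewma_components(w, params.tau1, params.tau2, params.tau3)
    yhat = params.y_star + params.k1 * a - params.k3 * c
    return yhat[days - 1]


def rss_dr(params: DRParams, w, days, y) -> float:
    """Residual sum of squares over performance days, in squared seconds."""
    y = np.asarray(y, dtype=float)
    if y.size == 0:
        raise ValueError("no performances supplied")
    yhat = predict_dr(w, params, days)
    if len(yhat) != len(y):
        raise ValueError("days and y must have equal length")
    return float(np.sum((yhat - y) ** 2))


def _profiled_rss(log_tau, w, days_idx, y, y_star):
    """RSS at given log time constants with (k1, k3) profiled out by LS."""
    tau1, tau2, tau3 = np.exp(log_tau)
    a, c = _ewma_components(w, tau1, tau2, tau3)
    design = np.column_stack([a[days_idx], -c[days_idx]])
    target = y - y_star
    coef, _, _, _ = np.linalg.lstsq(design, target, rcond=None)
    resid = target - design @ coef
    return float(resid @ resid), float(coef[0]), float(coef[1])


def fit_dr(
    w,
    days,
    y,
    y_star: float | None = None,
    bounds=DEFAULT_TAU_BOUNDS,
    n_starts: int = 8,
    seed: int = 0,
) -> DRFit:
    """Fit the variable dose-response model by multi-start RSS minimisation.

    Parameters
    ----------
    w : array-like
        Daily loads on the contiguous day grid 1..T.
    days, y : array-like
        Performance days (1-based day indices) and observed times (seconds).
    y_star : float, optional
        Fixed basic level of performance; defaults to the earliest observed
        performance.
    bounds : sequence of (low, high)
        Search bounds on (tau1, tau2, tau3), days.
    n_starts : int
        Number of quasi-Newton starts (one canonical start plus seeded
        log-uniform jitter within the bounds).
    seed : int
        Seed for the start jitter.

    Returns
    -------
    DRFit
        Best-of-starts parameters and diagnostics; ``at_bounds`` flags a time
        constant within 1% of a search bound.
    """
    w = _check_loads(w)
    y = np.asarray(y, dtype=float)
    days = _check_days(days, len(w))
    if len(y) != len(days):
        raise ValueError("days and y must have equal length")
    if len(y) < 6:
        raise ValueError(f"need at least 6 performances to fit 5 parameters, got {len(y)}")
    order = np.argsort(days, kind="stable")
    days, y = days[order], y[order]
    if y_star is None:
        y_star = float(y[0])
    days_idx = days - 1

    log_bounds = [(np.log(lo), np.log(hi)) for lo, hi in bounds]
    rng = np.random.default_rng(seed)
    starts = [np.log(np.clip(_TAU_START, [b[0] for b in bounds], [b[1] for b in bounds]))]
    for _ in range(max(0, n_starts - 1)):
        starts.append(np.array([rng.uniform(lo, hi) for lo, hi in log_bounds]))

    best = None
    start_rss = []
    any_converged = False
    for x0 in starts:
        res = minimize(
            lambda lt: _profiled_rss(lt, w, days_idx, y, y_star)[0],
            x0,
            method="L-BFGS-B",
            bounds=log_bounds,
            options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-10},
        )
        start_rss.append(float(res.fun))
        any_converged = any_converged or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not any_converged:
        raise RuntimeError(
            f"dose-response fit failed to converge from any of {len(starts)} starts; "
            f"per-start RSS: {start_rss}"
        )

    rss, k1, k3 = _profiled_rss(best.x, w, days_idx, y, y_star)
    tau = np.exp(best.x)
    at_bounds = any(
        t <= lo * 1.01 or t >= hi * 0.99 for t, (lo, hi) in zip(tau, bounds)
    )
    if at_bounds:
        logger.info("a fitted time constant sits at a search bound")
    params = DRParams(y_star=y_star, k1=k1, k3=k3, tau1=tau[0], tau2=tau[1], tau3=tau[2])
    return DRFit(
        params=params,
        rss=rss,
        n_obs=len(y),
        converged=True,
        n_starts_used=len(starts),
        start_rss=start_rss,
        at_bounds=at_bounds,
    )


class DoseResponseModel(BaseEstimator, RegressorMixin):
    """Dose-response regressor over (athlete, day) rows.

    Unlike the multivariate models this estimator consumes only the raw daily
    load series (supplied at construction, one per athlete) plus the
    ``athlete_id``/``day`` keys of each row; it fits one dose-response model
    per athlete present in the training rows.

    Parameters
    ----------
    loads : mapping
        ``athlete_id -> daily load array`` on the contiguous day grid.
    y_star : mapping or None
        Optional ``athlete_id -> basic performance level``; by default each
        athlete's earliest training observation is used.
    n_starts, seed, bounds : fitting controls passed to :func:`fit_dr`.
    """

    def __init__(self, loads=None, y_star=None, n_starts: int = 8, seed: int = 0,
                 bounds=DEFAULT_TAU_BOUNDS):
        self.loads = loads
        self.y_star = y_star
        self.n_starts = n_starts
        self.seed = seed
        self.bounds = bounds

    def fit(self, X: pd.DataFrame, y):
        if self.loads is None:
            raise ValueError("DoseResponseModel requires per-athlete daily loads")
        for col in ("athlete_id", "day"):
            if col not in X.columns:
                raise KeyError(f"missing required column {col!r}")
        y = np.asarray(y, dtype=float)
        self.fits_ = {}
        for aid, grp in X.groupby("athlete_id", sort=True, observed=True):
            if aid not in self.loads:
                raise KeyError(f"no load series supplied for athlete {aid!r}")
            idx = grp.index
            pos = X.index.get_indexer(idx)
            self.fits_[aid] = fit_dr(
                self.loads[aid],
                grp["day"].to_numpy(),
                y[pos],
                y_star=None if self.y_star is None else self.y_star[aid],
                n_starts=self.n_starts,
                seed=self.seed,
                bounds=self.bounds,
            )
        return self

    def predict(self, X: pd.DataFrame):
        if not hasattr(self, "fits_"):
            raise RuntimeError("model is not fitted")
        out = np.empty(len(X))
        for i, (aid, day) in enumerate(zip(X["athlete_id"], X["day"])):
            if aid not in self.fits_:
                raise KeyError(f"athlete {aid!r} was not seen during fitting")
            out[i] = predict_dr(self.loads[aid], self.fits_[aid].params, [int(day)])[0]
        return out
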