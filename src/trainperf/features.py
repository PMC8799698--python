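"""Design-matrix construction: the 19 predictors of the performance model.

Each performance row (athlete, trial day) is described by:

========  =============================================================
X1        total daily training load w(t) on the trial day
X2, X3    impulse / serial cumulative responses of w
X4..X15   impulse / serial cumulative responses of six daily session
          characteristics: RPE, mean power, max power, relative
          intensity, duration, density
X16       ice quality on the trial day (Borg CR 0-10)
X17       consecutive rest days immediately before the trial
X18       previous performance of the same athlete (lag 1)
X19       athlete id (group mode only)
========  =============================================================

Convolutions include the same-day term (l = t); the dose-response model's own
sums do not — that distinction belongs to :mod:`trainperf.dose_response`.
Same-day sessions are aggregated to one daily value before convolution:
durations sum, while RPE, powers, relative intensity and density are
duration-weighted means (power and intensity weighted by on-ice durations
only, since they are on-ice measures).  Days without sessions contribute 0.
"""

from __future__ import annotations

import datetime as dt
import logging

import numpy as np
import pandas as pd

from .kernels import KernelConfig, convolve_series

__all__ = [
    "LOAD_COMPONENTS",
    "default_load_rule",
    "daily_loads",
    "compute_rest_days",
    "build_design_matrix",
    "PREDICTOR_PROVENANCE",
]

logger = logging.getLogger(__name__)

LOAD_COMPONENTS = ("tl_ice", "tl_rt", "tl_aer", "tl_rs", "tl_act")

# session characteristic -> (column, weighting) for daily aggregation
_CHARACTERISTICS = (
    ("rpe", "all"),
    ("mean_power", "ice"),
    ("max_power", "ice"),
    ("relative_intensity", "ice"),
    ("duration", "sum"),
    ("density", "all"),
)

PREDICTOR_PROVENANCE = {
    "X1": {"source": "total_load", "kernel": None},
    "X2": {"source": "total_load", "kernel": "impulse"},
    "X3": {"source": "total_load", "kernel": "serial"},
    "X16": {"source": "ice_quality", "kernel": None},
    "X17": {"source": "rest_days", "kernel": None},
    "X18": {"source": "previous_performance", "kernel": None},
    "X19": {"source": "athlete_id", "kernel": None},
}
for _i, (_name, _) in enumerate(_CHARACTERISTICS):
    PREDICTOR_PROVENANCE[f"X{4 + 2 * _i}"] = {"source": _name, "kernel": "impulse"}
    PREDICTOR_PROVENANCE[f"X{5 + 2 * _i}"] = {"source": _name, "kernel": "serial"}


def default_load_rule(sessions: pd.DataFrame) -> pd.Series:
    """Total session load: sum of the five component loads.

    The component formulas themselves are federation-internal; this simple
    additive rule is the package default and any callable mapping a session
    frame to a per-session total can be substituted.
    """
    return sessions[list(LOAD_COMPONENTS)].sum(axis=1)


def _to_day(dates, start: dt.date) -> np.ndarray:
    days = np.array(
        [(pd.Timestamp(d).date() - start).days + 1 for d in dates], dtype=int
    )
    return days


def daily_loads(sessions: pd.DataFrame, period_days: int, start: dt.date,
                load_rule=default_load_rule) -> np.ndarray:
    """Total daily load w(t) on the grid 1..period_days for one athlete."""
    w = np.zeros(period_days)
    if len(sessions):
        totals = np.asarray(load_rule(sessions), dtype=float)
        days = _to_day(sessions["date"], start)
        if np.any(days < 1) or np.any(days > period_days):
            raise ValueError("session date outside the day grid")
        np.add.at(w, days - 1, totals)
    return w


def compute_rest_days(session_days, performance_day: int, period_days: int | None = None) -> int:
    """Consecutive days with no session immediately before a performance day.

    A last session 3 days before the trial leaves 2 empty days in between,
    hence 2 rest days.  Sessions on the performance day itself are ignored.
    """
    performance_day = int(performance_day)
    if performance_day < 1 or (period_days is not None and performance_day > period_days):
        raise ValueError(f"performance day {performance_day} outside the period")
    have = set(int(d) for d in session_days)
    rest = 0
    d = performance_day - 1
    while d >= 1 and d not in have:
        rest += 1
        d -= 1
    return rest


def _daily_characteristics(sessions: pd.DataFrame, period_days: int, start: dt.date) -> dict:
    """Aggregate same-day sessions into one daily value per characteristic."""
    out = {name: np.zeros(period_days) for name, _ in _CHARACTERISTICS}
    if not len(sessions):
        return out
    days = _to_day(sessions["date"], start)
    dur = sessions["duration"].to_numpy(dtype=float)
    ice = (sessions["modality"].to_numpy() == "ice").astype(float)
    for name, how in _CHARACTERISTICS:
        vals = sessions[name].to_numpy(dtype=float)
        if how == "sum":
            np.add.at(out[name], days - 1, vals)
            continue
        wts = dur * ice if how == "ice" else dur
        num = np.zeros(period_days)
        den = np.zeros(period_days)
        np.add.at(num, days - 1, vals * wts)
        np.add.at(den, days - 1, wts)
        nz = den > 0
        out[name][nz] = num[nz] / den[nz]
    return out


def build_design_matrix(
    sessions: pd.DataFrame,
    performances: pd.DataFrame,
    mode: str = "group",
    cfg: KernelConfig = KernelConfig(),
    load_rule=default_load_rule,
    period_days: int | None = None,
    start: dt.date | None = None,
):
    """Build the supervised design matrix, one row per performance.

    Parameters
    ----------
    sessions, performances : DataFrames in the cohort CSV schemas.
    mode : {"group", "individual"}
        Group mode adds the athlete-id predictor X19 (19 predictors);
        individual mode omits it (18).
    cfg : KernelConfig
        Kernel time constants for the cumulative responses.
    load_rule : callable
        Session frame -> per-session total load (default: component sum).
    period_days, start : optional
        Day-grid extent and day-1 date; inferred from the data when omitted.

    Returns
    -------
    (DataFrame, dict)
        The matrix carries key columns ``athlete_id``/``date``/``day``, the
        predictors ``X1..X18`` (+``X19`` in group mode) and the target ``y``
        (time in seconds).  Each athlete's first trial is dropped (no lag-1
        performance); athletes with fewer than 2 trials are excluded with a
        warning.  The dict maps predictor names to provenance plus the kernel
        constants.
    """
    if mode not in ("group", "individual"):
        raise ValueError(f"mode must be 'group' or 'individual', got {mode!r}")
    all_dates = list(performances["date"])
    if len(sessions):
        all_dates += list(sessions["date"])
    dates = [pd.Timestamp(d).date() for d in all_dates]
    if start is None:
        start = min(dates)
    if period_days is None:
        period_days = max((d - start).days + 1 for d in dates)

    rows = []
    for aid, perf in performances.groupby("athlete_id", sort=True):
        if len(perf) < 2:
            logger.warning(
                "athlete %s has %d performance(s); need >= 2 for the lag-1 "
                "predictor — excluded", aid, len(perf)
            )
            continue
        sess = sessions[sessions["athlete_id"] == aid] if len(sessions) else sessions
        w = daily_loads(sess, period_days, start, load_rule)
        conv = {
            "X2": convolve_series(w, "impulse", cfg),
            "X3": convolve_series(w, "serial", cfg),
        }
        daily = _daily_characteristics(sess, period_days, start)
        for i, (name, _) in enumerate(_CHARACTERISTICS):
            conv[f"X{4 + 2 * i}"] = convolve_series(daily[name], "impulse", cfg)
            conv[f"X{5 + 2 * i}"] = convolve_series(daily[name], "serial", cfg)
        session_days = _to_day(sess["date"], start) if len(sess) else []

        perf = perf.assign(day=_to_day(perf["date"], start)).sort_values("day")
        prev_time = None
        for _, rec in perf.iterrows():
            day = int(rec["day"])
            if prev_time is None:
                prev_time = float(rec["time_s"])
                continue
            row = {
                "athlete_id": aid,
                "date": pd.Timestamp(rec["date"]).date().isoformat(),
                "day": day,
                "X1": w[day - 1],
                **{k: v[day - 1] for k, v in conv.items()},
                "X16": float(rec["ice_quality"]),
                "X17": compute_rest_days(session_days, day, period_days),
                "X18": prev_time,
                "y": float(rec["time_s"]),
            }
            if mode == "group":
                row["X19"] = aid
            rows.append(row)
            prev_time = float(rec["time_s"])

    predictors = [f"X{i}" for i in range(1, 19)] + (["X19"] if mode == "group" else [])
    columns = ["athlete_id", "date", "day"] + predictors + ["y"]
    dm = pd.DataFrame(rows, columns=columns)
    dm = dm.sort_values(["day", "athlete_id"], kind="stable").reset_index(drop=True)
    meta = {
        "mode": mode,
        "predictors": predictors,
        "provenance": {k: PREDICTOR_PROVENANCE[k] for k in predictors},
        "kernel": {"tau_i": cfg.tau_i, "tau_g": cfg.tau_g, "tau_d": cfg.tau_d, "td": cfg.delay},
        "period_days": int(period_days),
        "start": start.isoformat(),
    }
    return dm, meta
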