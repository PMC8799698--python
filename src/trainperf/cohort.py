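"""Seeded synthetic cohorts of elite short-track speed skaters.

The generator emulates the statistical structure of a three-month monitoring
block in a small national squad: 7 athletes (3 male, 4 female), roughly
16.6 +/- 2.5 h of training per week spread over ~10 sessions on Monday to
Saturday, a two-week complete break in the middle of the period, and standing
start time trials over 166.68 m (1.5 lap) three times per active week —
about 35 trials per athlete, ~250 in total.

True performances are produced by a per-athlete variable dose-response process
driven by the simulated daily loads, plus small covariate effects (ice quality
on the trial day, freshness from preceding rest days) and i.i.d. Gaussian
timing noise.  Ground-truth dose-response parameters are drawn per athlete
from ranges typical of fitted values in this population, so the generating
process is recoverable by the fitting code.

Everything is deterministic given the config seed.
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .dose_response import DRParams, predict_dr
from .features import LOAD_COMPONENTS, compute_rest_days, daily_loads

__all__ = [
    "CohortConfig",
    "AthleteProfile",
    "SESSION_COLUMNS",
    "PERFORMANCE_COLUMNS",
    "generate_cohort",
    "simulate_true_performance",
    "write_cohort",
]

SESSION_COLUMNS = (
    "athlete_id",
    "date",
    *LOAD_COMPONENTS,
    "rpe",
    "mean_power",
    "max_power",
    "relative_intensity",
    "duration",
    "density",
    "modality",
)

PERFORMANCE_COLUMNS = ("athlete_id", "date", "time_s", "ice_quality")

# Ground-truth dose-response parameter ranges (per-athlete uniform draws):
# gains in s per load unit (k1) and s per squared-load-unit-day (k3), time
# constants in days.  Negative gains: with time as the outcome, training
# lowers the time (aptitude) while accumulated dose raises it (fatigue).
_K1_RANGE = (-4.9e-5, -3.2e-5)
_K3_RANGE = (-1.7e-8, -4.0e-9)
_TAU1_RANGE = (26.0, 42.0)
_TAU2_RANGE = (15.0, 26.0)
_TAU3_RANGE = (4.3, 6.7)


@dataclass(frozen=True)
class CohortConfig:
    """Configuration of the synthetic cohort.

    Defaults reproduce the study conditions: 7 athletes, a 98-day period with
    a two-week break starting day 43, ~10 sessions and 16.6 +/- 2.5 training
    hours per week, time trials on Tuesday/Thursday/Saturday, 0.05 s timing
    noise.  ``performance_weekdays`` are offsets from Monday (0).
    """

    n_athletes: int = 7
    n_males: int = 3
    period_days: int = 98
    break_start: int = 43
    break_len: int = 14
    sessions_per_week: int = 10
    weekly_volume_mean: float = 16.6
    weekly_volume_sd: float = 2.5
    performance_weekdays: tuple = (1, 3, 5)
    trial_distance: float = 166.68
    noise_sd: float = 0.05
    ice_quality_slope: float = -0.02
    rest_effect: float = -0.01
    p_ice: float = 0.6
    start_date: str = "2021-05-03"  # a Monday: day 1 of the period
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_athletes", "period_days", "sessions_per_week", "break_len"):
            if not getattr(self, name) > 0:
                raise ValueError(f"config field {name} must be positive, got {getattr(self, name)}")
        if not 0 <= self.n_males <= self.n_athletes:
            raise ValueError(f"config field n_males must lie in [0, n_athletes], got {self.n_males}")
        if not (1 <= self.break_start and self.break_start + self.break_len - 1 <= self.period_days):
            raise ValueError(
                f"config field break_start/break_len: break window "
                f"[{self.break_start}, {self.break_start + self.break_len - 1}] "
                f"must lie inside [1, {self.period_days}]"
            )
        if self.noise_sd < 0:
            raise ValueError(f"config field noise_sd must be >= 0, got {self.noise_sd}")
        if not all(0 <= d <= 6 for d in self.performance_weekdays):
            raise ValueError("config field performance_weekdays must contain weekday offsets in [0, 6]")
        if self.weekly_volume_mean <= 0 or self.weekly_volume_sd < 0:
            raise ValueError("config field weekly_volume_mean/sd must be positive / non-negative")

    @property
    def start(self) -> dt.date:
        return dt.date.fromisoformat(self.start_date)

    def in_break(self, day: int) -> bool:
        return self.break_start <= day < self.break_start + self.break_len

    def date_of(self, day: int) -> dt.date:
        return self.start + dt.timedelta(days=day - 1)


@dataclass(frozen=True)
class AthleteProfile:
    """Ground truth for one synthetic athlete."""

    athlete_id: str
    sex: str
    body_mass: float
    baseline_time: float
    dr_params: DRParams
    ice_quality_slope: float
    rest_effect: float

    def __post_init__(self) -> None:
        if not self.baseline_time > 0:
            raise ValueError("baseline_time must be > 0")


def _draw_profile(i: int, cfg: CohortConfig, rng: np.random.Generator) -> AthleteProfile:
    male = i < cfg.n_males
    body_mass = rng.normal(71.4, 9.4) if male else rng.normal(55.9, 3.9)
    baseline = rng.normal(16.6 if male else 17.6, 0.3)
    params = DRParams(
        y_star=baseline,
        k1=rng.uniform(*_K1_RANGE),
        k3=rng.uniform(*_K3_RANGE),
        tau1=rng.uniform(*_TAU1_RANGE),
        tau2=rng.uniform(*_TAU2_RANGE),
        tau3=rng.uniform(*_TAU3_RANGE),
    )
    return AthleteProfile(
        athlete_id=f"ath{i + 1:02d}",
        sex="M" if male else "F",
        body_mass=float(body_mass),
        baseline_time=float(baseline),
        dr_params=params,
        ice_quality_slope=cfg.ice_quality_slope,
        rest_effect=cfg.rest_effect,
    )


def _week_starts(cfg: CohortConfig):
    return range(1, cfg.period_days + 1, 7)


def _generate_sessions(
    profile: AthleteProfile, cfg: CohortConfig, rng: np.random.Generator
) -> pd.DataFrame:
    rows = []
    for wk_start in _week_starts(cfg):
        week_days = [d for d in range(wk_start, min(wk_start + 7, cfg.period_days + 1))]
        # Sundays (offset 6) are off; break days carry no sessions at all.
        candidates = [
            d for d in week_days if (d - wk_start) < 6 and not cfg.in_break(d)
        ]
        if not candidates:
            continue
        active_frac = len([d for d in week_days if not cfg.in_break(d)]) / 7.0
        volume_h = max(rng.normal(cfg.weekly_volume_mean, cfg.weekly_volume_sd), 6.0)
        volume_h *= active_frac
        n_sess = max(1, round(cfg.sessions_per_week * active_frac))
        days = rng.choice(candidates, size=n_sess, replace=True)
        weights = rng.dirichlet(np.full(n_sess, 8.0))
        for day, wt in zip(np.sort(days), weights):
            duration = volume_h * 60.0 * wt
            on_ice = rng.random() < cfg.p_ice
            rpe = float(np.clip(rng.normal(6.0, 1.5), 1.0, 10.0))
            load = rpe * duration
            if on_ice:
                mean_power = float(rng.normal(250.0 if profile.sex == "M" else 180.0, 25.0))
                max_power = mean_power * rng.uniform(1.3, 1.6)
                rel_int = float(rng.uniform(0.6, 0.95))
                comp = {"tl_ice": 0.8 * load, "tl_rt": 0.0, "tl_aer": 0.0,
                        "tl_rs": 0.2 * load, "tl_act": 0.0}
            else:
                mean_power = 0.0
                max_power = 0.0
                rel_int = 0.0
                comp = {"tl_ice": 0.0, "tl_rt": 0.5 * load, "tl_aer": 0.4 * load,
                        "tl_rs": 0.0, "tl_act": 0.1 * load}
            rows.append(
                {
                    "athlete_id": profile.athlete_id,
                    "date": cfg.date_of(int(day)).isoformat(),
                    **comp,
                    "rpe": rpe,
                    "mean_power": mean_power,
                    "max_power": float(max_power),
                    "relative_intensity": rel_int,
                    "duration": float(duration),
                    "density": float(rng.uniform(0.3, 0.9)),
                    "modality": "ice" if on_ice else "off",
                }
            )
    return pd.DataFrame(rows, columns=list(SESSION_COLUMNS))


def _default_performance_days(cfg: CohortConfig):
    days = []
    for wk_start in _week_starts(cfg):
        for offset in cfg.performance_weekdays:
            d = wk_start + offset
            if d <= cfg.period_days and not cfg.in_break(d):
                days.append(d)
    return days


def simulate_true_performance(
    load_series,
    profile: AthleteProfile,
    config: CohortConfig,
    performance_days=None,
    session_days=(),
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Emit performance records from the athlete's ground-truth process.

    ``time_s(t)`` is the dose-response prediction at day ``t`` from the
    profile's parameters, plus the ice-quality and rest covariate effects and
    Gaussian noise with sd ``config.noise_sd``; records are emitted only on
    the performance days.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    w = np.asarray(load_series, dtype=float)
    if len(w) != config.period_days:
        raise ValueError("load_series must be aligned to the day grid (period_days long)")
    if performance_days is None:
        performance_days = _default_performance_days(config)
    session_days = sorted(set(int(d) for d in session_days))
    rows = []
    for day in performance_days:
        base = predict_dr(w, profile.dr_params, [int(day)])[0]
        ice_q = float(np.clip(rng.normal(6.0, 1.5), 0.0, 10.0))
        rest = compute_rest_days(session_days, int(day), period_days=config.period_days)
        time_s = (
            base
            + profile.ice_quality_slope * (ice_q - 5.0)
            + profile.rest_effect * rest
            + rng.normal(0.0, config.noise_sd)
        )
        rows.append(
            {
                "athlete_id": profile.athlete_id,
                "date": config.date_of(int(day)).isoformat(),
                "time_s": float(time_s),
                "ice_quality": ice_q,
            }
        )
    return pd.DataFrame(rows, columns=list(PERFORMANCE_COLUMNS))


def generate_cohort(config: CohortConfig = CohortConfig()):
    """Generate a full synthetic cohort.

    Returns
    -------
    profiles : list of AthleteProfile
    sessions : pandas.DataFrame with SESSION_COLUMNS
    performances : pandas.DataFrame with PERFORMANCE_COLUMNS
    """
    rng = np.random.default_rng(config.seed)
    profiles, session_frames, perf_frames = [], [], []
    for i in range(config.n_athletes):
        profile = _draw_profile(i, config, rng)
        sessions = _generate_sessions(profile, config, rng)
        w = daily_loads(sessions, config.period_days, config.start)
        session_days = [
            (dt.date.fromisoformat(d) - config.start).days + 1 for d in sessions["date"]
        ]
        perfs = simulate_true_performance(
            w, profile, config, session_days=session_days, rng=rng
        )
        profiles.append(profile)
        session_frames.append(sessions)
        perf_frames.append(perfs)
    sessions = pd.concat(session_frames, ignore_index=True)
    performances = pd.concat(perf_frames, ignore_index=True)
    return profiles, sessions, performances


def write_cohort(profiles, sessions: pd.DataFrame, performances: pd.DataFrame, out_dir) -> dict:
    """Persist a cohort as sessions.csv / performances.csv / ground_truth.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "sessions": out / "sessions.csv",
        "performances": out / "performances.csv",
        "ground_truth": out / "ground_truth.json",
    }
    sessions.to_csv(paths["sessions"], index=False)
    performances.to_csv(paths["performances"], index=False)
    truth = [asdict(p) for p in profiles]
    paths["ground_truth"].write_text(json.dumps(truth, indent=2, sort_keys=True))
    return {k: str(v) for k, v in paths.items()}
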