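# trainperf

Training-load response modelling for elite sport, with generalisation as the
first-class evaluation criterion.

Coaches and sport scientists log daily training sessions (load, RPE, power,
duration, ...) and periodic performance tests — here standing-start time
trials over 166.68 m (1.5 lap) in short-track speed skating, timed in
seconds, lower is better.  The question this package answers end to end is:
*given the training diary up to today, how well can tomorrow's trial be
forecast, and which model class transfers best to unseen weeks?*

Four modelling routes share one fit/predict contract:

* **DR** — the variable dose-response impulse-response model, fitted per
  athlete from the raw daily loads w(t):

  ```
  ŷ(t) = y* + k₁ Σ_{l<t} w(l) e^(−(t−l)/τ₁) − Σ_{l<t} k₂(l) w(l) e^(−(t−l)/τ₂)
  k₂(l) = k₃ Σ_{m≤l} w(m) e^(−(l−m)/τ₃)
  ```

  with the five parameters (k₁, k₃, τ₁, τ₂, τ₃) estimated by RSS
  minimisation (variable projection + quasi-Newton multi-start) and y* held
  fixed.
* **ENET** — elastic net on a 19-predictor design matrix
  (`½‖y − Xβ‖² + λ((1−α)‖β‖² + α‖β‖₁)`), mixing ridge and lasso.
* **PCR** — principal component regression with Kaiser-rule component
  selection (correlation-matrix eigenvalue > 1).
* **RF** — random forest regression (`mtry` candidate variables per split).

The design matrix accumulates daily series with two fixed kernels — an
impulse decay `e^(−t/τ_I)` (τ_I = 3 d) and a serial bi-exponential
growth-then-decay response (τ_G = 1 d, τ_D = 7 d, delay TD = 4τ_G) — and adds
ice quality, rest days, the lag-1 performance and (pooled mode) the athlete
id.  All models are selected and evaluated with time-ordered
cross-validation: expanding-window folds on the first 80% of observations
choose hyper-parameters by mean validation RMSE, then a rolling forecasting
origin walks through the held-out 20%, refitting on everything strictly
before each block.  Reported criteria are RMSE, MAE, R² and the
generalisation gap (evaluation − training RMSE).

Because elite monitoring data cannot be redistributed, the package includes a
seeded synthetic-cohort generator (7 skaters, ~3 months with a two-week
break, 16.6 ± 2.5 h/week, ~250 trials) whose ground truth is a per-athlete
dose-response process plus covariate effects and timing noise — every stage
of the pipeline is testable offline against known parameters.  See
`docs/methods.md` for the full model and design notes.

## Worked example

```python
import pandas as pd
import trainperf as tp

cfg = tp.CohortConfig(seed=7)                       # study-scale synthetic squad
profiles, sessions, perfs = tp.generate_cohort(cfg)
print("cohort:", len(profiles), "athletes,", len(sessions), "sessions,", len(perfs), "trials")

# fit the dose-response reference for one athlete
w = tp.daily_loads(sessions[sessions.athlete_id == "ath01"], cfg.period_days, cfg.start)
sub = perfs[perfs.athlete_id == "ath01"]
days = [(pd.Timestamp(d).date() - cfg.start).days + 1 for d in sub["date"]]
fit = tp.fit_dr(w, days, sub["time_s"].to_numpy(), seed=0)
p = fit.params
print(f"DR fit ath01: k1={p.k1:.3e} k3={p.k3:.3e} tau1={p.tau1:.1f} "
      f"tau2={p.tau2:.1f} tau3={p.tau3:.1f} rss={fit.rss:.4f}")

# compare model families under rolling-origin evaluation
run = tp.RunConfig(cohort=cfg, seed=7,
                   families=(("dr", "individual"), ("enet", "group"), ("pcr", "group")))
res = tp.run_study(run, sessions=sessions, performances=perfs)
print(res.summary[["rmse_mean", "rmse_sd", "mae_mean", "gap_mean", "n_blocks"]].round(4))
```

Output:

```
cohort: 7 athletes, 840 sessions, 252 trials
DR fit ath01: k1=-2.944e-05 k3=-1.229e-08 tau1=11.6 tau2=14.7 tau3=4.6 rss=0.0861
        rmse_mean  rmse_sd  mae_mean  gap_mean  n_blocks
DR_I       0.0519   0.0202    0.0466   -0.0011        21
ENET_G     0.0734   0.0140    0.0608   -0.0009         3
PCR_G      0.1334   0.0160    0.1074    0.0162         3
```

Reading this: the per-athlete dose-response model forecasts held-out trials
to ~0.05 s — the generator's noise floor — because the synthetic ground truth
*is* a dose-response process with small covariate effects; the pooled elastic
net sits at ~0.07 s and PCR, limited to a few principal components, at
~0.13 s.  Gaps near zero mean no overfitting.  When the generator is switched
to a covariate-dominant configuration (strong ice-quality and freshness
effects the univariate model cannot see), the ordering reverses and the
pooled elastic net wins in most replicates — that experiment is packaged as
`trainperf.pipeline.generalisation_echo`.

The same pipeline is scriptable from a shell:

```bash
trainperf simulate --seed 7 --out cohort/
trainperf features --sessions cohort/sessions.csv --performances cohort/performances.csv --out feat/
trainperf fit-dr --sessions cohort/sessions.csv --performances cohort/performances.csv --athlete ath01
trainperf run-all --seed 7 --out study/        # full selection + evaluation + summary
```

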