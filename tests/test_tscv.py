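import math

import numpy as np
import pandas as pd
import pytest

from trainperf.cohort import CohortConfig, generate_cohort
from trainperf.dose_response import DoseResponseModel, predict_dr
from trainperf.features import build_design_matrix, daily_loads
from trainperf.metrics import compute_metrics
from trainperf.models import EstimatorSpec
from trainperf.tscv import evaluate_model, make_fold_plan, select_model


class TestFoldPlan:
    def test_hand_enumerated_example(self):
        plan = make_fold_plan(np.arange(1, 11), K=2, eval_frac=0.2, valid_len=2)
        # n=10: eval tail = observations 9, 10 (positions 8, 9)
        assert list(np.concatenate(plan.eval_blocks)) == [8, 9]
        (tr1, va1), (tr2, va2) = plan.folds
        assert list(tr1) == [0, 1, 2, 3] and list(va1) == [4, 5]
        assert list(tr2) == [0, 1, 2, 3, 4, 5] and list(va2) == [6, 7]

    def test_train_always_precedes_valid(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            n = int(rng.integers(30, 120))
            K = int(rng.integers(2, 6))
            t = np.sort(rng.uniform(0, 1000, n))
            try:
                plan = make_fold_plan(t, K=K, eval_frac=0.2)
            except ValueError:
                continue
            for tr, va in plan.folds:
                assert tr.max() < va.min()
                assert len(tr) > 0

    def test_eval_size_ceil_rule(self):
        plan = make_fold_plan(np.arange(248), K=5, eval_frac=0.2)
        assert sum(len(b) for b in plan.eval_blocks) == math.ceil(0.2 * 248)
        assert len(plan.selection) == 248 - 50

    def test_eval_blocks_disjoint_from_selection_and_tiled(self):
        plan = make_fold_plan(np.arange(100), K=5, eval_frac=0.2, eval_len=7)
        eval_all = np.concatenate(plan.eval_blocks)
        assert set(eval_all).isdisjoint(set(plan.selection))
        assert [len(b) for b in plan.eval_blocks] == [7, 7, 6]  # partial final kept

    def test_infeasible_plan_reports_constraint(self):
        with pytest.raises(ValueError, match="K.?valid_len|selection"):
            make_fold_plan(np.arange(12), K=5, eval_frac=0.2, valid_len=4)

    def test_deterministic(self):
        t = np.random.default_rng(0).uniform(0, 10, 50)
        p1 = make_fold_plan(t, K=3, eval_frac=0.25)
        p2 = make_fold_plan(t, K=3, eval_frac=0.25)
        assert np.array_equal(p1.order, p2.order)
        for (a1, b1), (a2, b2) in zip(p1.folds, p2.folds):
            assert np.array_equal(a1, a2) and np.array_equal(b1, b2)


@pytest.fixture(scope="module")
def group_data():
    cfg = CohortConfig(seed=21)
    _, sessions, perfs = generate_cohort(cfg)
    dm, _ = build_design_matrix(sessions, perfs, "group",
                                period_days=cfg.period_days, start=cfg.start)
    loads = {
        aid: daily_loads(sessions[sessions["athlete_id"] == aid], cfg.period_days, cfg.start)
        for aid in sessions["athlete_id"].unique()
    }
    plan = make_fold_plan(dm["day"].to_numpy(), K=5, eval_frac=0.2, eval_len=21)
    return cfg, dm, loads, plan


class TestSelection:
    def test_single_candidate_returned(self, group_data):
        _, dm, loads, plan = group_data
        spec = EstimatorSpec("enet", "group", {"alpha": 0.5, "lam": 0.1})
        sel = select_model([spec], dm, plan)
        assert sel.winner is spec
        assert sel.scores.shape == (1, plan.K + 1)

    def test_dominating_candidate_wins(self, group_data):
        _, dm, loads, plan = group_data
        good = EstimatorSpec("enet", "group", {"alpha": 0.25, "lam": 0.01})
        bad = EstimatorSpec("enet", "group", {"alpha": 1.0, "lam": 1e6})  # intercept-only
        sel = select_model([bad, good], dm, plan)
        assert sel.winner is good
        assert (
            sel.scores.loc[good.label()].iloc[: plan.K]
            < sel.scores.loc[bad.label()].iloc[: plan.K]
        ).all()

    def test_winner_matches_score_table_argmin(self, group_data):
        _, dm, loads, plan = group_data
        cands = [
            EstimatorSpec("enet", "group", {"alpha": a, "lam": l})
            for a in (0.0, 1.0)
            for l in (0.01, 1.0)
        ]
        sel = select_model(cands, dm, plan)
        best_label = sel.scores["mean_rmse"].idxmin()
        assert sel.winner.label() == best_label


class TestEvaluation:
    def test_rolling_origin_refits_only_on_past(self, group_data):
        _, dm, loads, plan = group_data
        spec = EstimatorSpec("enet", "group", {"alpha": 0.25, "lam": 0.1})
        base = evaluate_model(spec, dm, plan)
        assert len(base.blocks) == len(plan.eval_blocks)
        # mutate all observations strictly after the first eval block
        first_end = len(plan.selection) + len(plan.eval_blocks[0])
        tainted = dm.copy()
        later = plan.order[first_end:]
        tainted.loc[tainted.index[later], "y"] += 5.0
        tainted.loc[tainted.index[later], ["X1", "X18"]] *= 10.0
        again = evaluate_model(spec, tainted, plan)
        b0, t0 = base.blocks[0], again.blocks[0]
        assert b0["eval"].rmse == t0["eval"].rmse  # bit-identical predictions
        assert b0["train"].rmse == t0["train"].rmse

    def test_noiseless_ground_truth_family_reaches_zero_error(self):
        cfg = CohortConfig(seed=5, noise_sd=0.0, ice_quality_slope=0.0, rest_effect=0.0)
        profiles, sessions, perfs = generate_cohort(cfg)
        dm, _ = build_design_matrix(sessions, perfs, "individual",
                                    period_days=cfg.period_days, start=cfg.start)
        sub = dm[dm["athlete_id"] == "ath01"].reset_index(drop=True)
        loads = {"ath01": daily_loads(sessions[sessions["athlete_id"] == "ath01"],
                                      cfg.period_days, cfg.start)}
        plan = make_fold_plan(sub["day"].to_numpy(), K=3, eval_frac=0.2, eval_len=3)
        # generating family with the true basic performance level supplied
        oracle = DoseResponseModel(loads=loads,
                                   y_star={"ath01": profiles[0].baseline_time}, seed=0)
        res = evaluate_model(oracle, sub, plan)
        assert res.completed_blocks()
        for block in res.completed_blocks():
            assert block["eval"].rmse <= 1e-6

    def test_known_noise_floor_with_true_parameters(self):
        # predictions from the generating parameters leave only the 0.05 s noise
        rmses = []
        for seed in (31, 32, 33):
            cfg = CohortConfig(seed=seed, ice_quality_slope=0.0, rest_effect=0.0)
            profiles, sessions, perfs = generate_cohort(cfg)
            resid = []
            for p in profiles:
                w = daily_loads(sessions[sessions["athlete_id"] == p.athlete_id],
                                cfg.period_days, cfg.start)
                sub = perfs[perfs["athlete_id"] == p.athlete_id]
                days = [(pd.Timestamp(d).date() - cfg.start).days + 1 for d in sub["date"]]
                yhat = predict_dr(w, p.dr_params, days)
                resid.extend(sub["time_s"].to_numpy() - yhat)
            rmses.append(float(np.sqrt(np.mean(np.square(resid)))))
        assert 0.05 * 0.85 <= np.mean(rmses) <= 0.05 * 1.15

    def test_failed_block_is_flagged_not_fatal(self, group_data):
        _, dm, loads, plan = group_data
        # dose-response without load series cannot fit: every block fails
        res = evaluate_model(EstimatorSpec("dr", "individual"), dm, plan, loads=None)
        assert all(b["failed"] for b in res.blocks)
        assert res.completed_blocks() == []
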