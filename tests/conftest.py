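import numpy as np
import pandas as pd
import pytest

from trainperf.cohort import CohortConfig, generate_cohort
from trainperf.features import build_design_matrix, daily_loads


@pytest.fixture(scope="session")
def default_cohort():
    """One default-condition synthetic cohort, shared across tests."""
    cfg = CohortConfig(seed=7)
    profiles, sessions, performances = generate_cohort(cfg)
    return cfg, profiles, sessions, performances


@pytest.fixture(scope="session")
def design_group(default_cohort):
    cfg, _, sessions, performances = default_cohort
    dm, meta = build_design_matrix(
        sessions, performances, "group", period_days=cfg.period_days, start=cfg.start
    )
    return dm, meta


@pytest.fixture(scope="session")
def athlete_loads(default_cohort):
    cfg, _, sessions, _ = default_cohort
    return {
        aid: daily_loads(sessions[sessions["athlete_id"] == aid], cfg.period_days, cfg.start)
        for aid in sessions["athlete_id"].unique()
    }


@pytest.fixture()
def toy_xy():
    """Small random regression problem as a DataFrame + target."""
    rng = np.random.default_rng(42)
    X = pd.DataFrame(rng.normal(size=(40, 5)), columns=[f"X{i}" for i in range(1, 6)])
    beta = np.array([1.0, -2.0, 0.5, 0.0, 3.0])
    y = X.to_numpy() @ beta + rng.normal(0, 0.3, 40) + 10.0
    return X, y
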