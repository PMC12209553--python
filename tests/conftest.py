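import numpy as np
import pandas as pd
import pytest

from cfrail.dataprep import (
    CountingProcessTable,
    SubjectEventHistory,
    build_counting_process,
)
from cfrail.simulate import SimulationConfig, simulate_trial


def random_histories(rng, n_subjects=12, n_clusters=3, window=122.0, max_events=4,
                     covariate=True):
    """Small random event histories for property tests."""
    out = []
    for i in range(n_subjects):
        times = np.sort(rng.uniform(1, window - 1, rng.integers(0, max_events + 1)))
        cov = {"age": float(rng.uniform(5, 16))} if covariate else {}
        out.append(
            SubjectEventHistory(
                subject_id=f"s{i}",
                cluster_id=f"c{i % n_clusters}",
                arm=int(i % 2),
                event_times=times.tolist(),
                followup_end=window,
                covariates=cov,
            )
        )
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def separation_table():
    """Two subjects, one binary covariate, monotone partial likelihood."""
    df = pd.DataFrame(
        {
            "subject_id": ["a", "b"],
            "cluster_id": ["c1", "c2"],
            "stratum": [1, 1],
            "start": [0.0, 0.0],
            "stop": [1.0, 2.0],
            "status": [1, 1],
            "arm": [1, 0],
        }
    )
    return CountingProcessTable(df, "gap", [])


@pytest.fixture(scope="session")
def small_trial():
    """One modest simulated cluster trial shared across tests."""
    cfg = SimulationConfig(n_clusters=20, subjects_per_cluster=15, seed=5)
    histories, truth = simulate_trial(cfg)
    table = build_counting_process(histories, cfg.window, clock="gap")
    return cfg, histories, truth, table
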