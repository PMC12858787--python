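import numpy as np
import pandas as pd
import pytest

from mmiprobit import (
    CategoryRange,
    MMIDataset,
    SimulationConfig,
    fit_cpmm,
    reference_cohort,
    simulate_cohort,
)


def small_config(seed: int = 1, **overrides) -> SimulationConfig:
    """Reduced cohort: 100 candidates over 3 days x 2 circuits, 30 interviewers."""
    kw = dict(n_candidates=100, n_interviewers=30, n_days=3, circuits_per_day=2)
    kw.update(overrides)
    return reference_cohort(seed=seed, **kw)


@pytest.fixture(scope="session")
def small_cohort():
    return simulate_cohort(small_config(seed=1))


@pytest.fixture(scope="session")
def small_model(small_cohort):
    model = fit_cpmm(small_cohort.dataset)
    assert model.converged
    return model


@pytest.fixture()
def toy_dataset():
    """4 candidates x 3 stations, hand-enumerable."""
    rows = []
    scores = {
        "C1": (10, 11, 12),
        "C2": (9, 10, 10),
        "C3": (13, 14, 15),
        "C4": (7, 8, 9),
    }
    for cand, vals in scores.items():
        for k, s in enumerate(vals):
            rows.append((cand, f"I{k+1}", f"S{k+1}", "D1", s))
    df = pd.DataFrame(
        rows, columns=["candidate", "interviewer", "station", "day", "score"]
    )
    return MMIDataset(df, CategoryRange(3, 15))
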