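"""Shared fixtures: one default synthetic cohort, generated once per session."""

import numpy as np
import pandas as pd
import pytest

import dietchoice as dc

COHORT_SEED = 20260926


@pytest.fixture(scope="session")
def cohort():
    """Default synthetic cohort (n=500, 50 foods, 49 trials each)."""
    cfg = dc.SimulationConfig(seed=COHORT_SEED)
    demo, items, ratings, trials, truth = dc.generate_cohort(cfg)
    return {
        "config": cfg,
        "demographics": demo,
        "tfeq_items": items,
        "ratings": ratings,
        "trials": trials,
        "truth": truth,
    }


@pytest.fixture(scope="session")
def cohort_scores(cohort):
    return dc.score_tfeq(cohort["tfeq_items"])


@pytest.fixture(scope="session")
def cohort_outcomes(cohort):
    return dc.score_task(cohort["trials"], cohort["ratings"])


@pytest.fixture(scope="session")
def cohort_trimmed(cohort):
    derived = dc.derive_trials(cohort["trials"], cohort["ratings"])
    trimmed, report = dc.filter_rt_outliers(derived)
    return trimmed, report


def normal_equations(X, y):
    """Independent OLS oracle: solve (X'X) b = X'y with an intercept column."""
    X = np.column_stack([np.ones(len(X)), np.asarray(X, float)])
    y = np.asarray(y, float)
    return np.linalg.solve(X.T @ X, X.T @ y)
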