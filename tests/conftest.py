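import numpy as np
import pandas as pd
import pytest

import tinnipy as tp
from tinnipy import pipeline


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def quiet_cfg():
    """Noise-free, deterministic-amplitude configuration."""
    return tp.SimConfig(
        baseline_noise_sd=0.0,
        startle_amp_sigma=0.0,
        gap_suppression=0.0,
        prepulse_suppression=0.0,
        habituation_decay=1.0,
    )


@pytest.fixture(scope="session")
def small_cohort():
    """A 10-animal cohort shared across tests that only read it."""
    rng = np.random.default_rng(42)
    cohort = tp.simulate_cohort(tp.SimConfig(), tp.CohortSpec(n_animals=10), rng)
    return cohort


@pytest.fixture(scope="session")
def small_cohort_results(small_cohort):
    return pipeline.score_cohort(small_cohort)


def make_result_row(
    phase="post_trauma",
    week=1,
    session_id="S001",
    test_type="GPIAS",
    frequency_khz=8.0,
    passed=True,
    percent_suppression=50.0,
):
    return {
        "phase": phase,
        "week": week,
        "session_id": session_id,
        "test_type": test_type,
        "frequency_khz": frequency_khz,
        "passed": passed,
        "percent_suppression": percent_suppression,
    }


@pytest.fixture
def result_table_builder():
    def build(rows):
        return pd.DataFrame([make_result_row(**r) for r in rows])

    return build
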