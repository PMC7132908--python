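import numpy as np
import pandas as pd
import pytest
from dataclasses import replace

import sparsecode as sc


@pytest.fixture(scope="session")
def small_pop():
    """Reduced population spec with no shared gain or arousal modulation,
    so analytic Poisson oracles apply exactly."""
    return replace(sc.V1_DEFAULT.population, n_units=12,
                   shared_gain_sd=0.0, arousal_gain=1.0)


@pytest.fixture(scope="session")
def small_schedule():
    return sc.default_schedule(n_per_condition=15, n_zero_contrast=24)


@pytest.fixture(scope="session")
def small_session(small_pop, small_schedule):
    return sc.simulate_session(small_pop, small_schedule, seed=42,
                               session_id="fix0")


@pytest.fixture
def trial_table():
    """Tiny well-formed behavioral trial table."""
    return pd.DataFrame({
        "subject_id": ["s0", "s0", "s0"],
        "trial_index": [0, 1, 2],
        "orientation_label": ["left", "right", "none"],
        "orientation_deg": [135.0, 45.0, np.nan],
        "contrast": [1.0, 0.15, 0.0],
        "duration_ms": [100.0, 50.0, 100.0],
        "response": ["left", "left", "right"],
        "correct": [True, False, False],
        "reaction_time_s": [0.8123456789012345, 1.5, 0.3],
    })
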