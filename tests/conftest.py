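import numpy as np
import pandas as pd
import pytest

from hapticube.pipeline import trial_metrics_table
from hapticube.synthetic import GroupPreset, generate_cohort, generate_session


@pytest.fixture
def rng():
    return np.random.default_rng(0)


SMALL_PRESET = GroupPreset(
    target_active_cells=4.5,
    target_smc=0.8,
    total_rotation=200.0,
    n_episodes=5,
    trial_duration=25.0,
)


@pytest.fixture
def small_session():
    """One short synthetic session (1 trial pair) with irregular sampling."""
    return generate_session(SMALL_PRESET, n_trials=1, seed=3, participant_id="P01", group="SI")


@pytest.fixture(scope="session")
def cohort42():
    """The default synthetic cohort (CB 6 / LB 10 / SI 16, master seed 42)."""
    return generate_cohort(seed=42)


@pytest.fixture(scope="session")
def cohort42_metrics(cohort42):
    tables = [trial_metrics_table(samples, anns) for samples, anns, _ in cohort42]
    return pd.concat(tables, ignore_index=True)
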