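import numpy as np
import pandas as pd
import pytest

from emascan import EpochSeries, SyntheticConfig, simulate_study


def make_series(counts, start="2024-01-01 00:00", epoch=1.0, wear=None, subject="s1"):
    counts = np.asarray(counts, dtype=float)
    if wear is None:
        wear = ~np.isnan(counts)
    return EpochSeries(
        subject_id=subject,
        start_time=pd.Timestamp(start),
        epoch_length=epoch,
        counts=counts,
        wear=np.asarray(wear, dtype=bool),
    )


@pytest.fixture
def day_series():
    """One full day of 1-min epochs with counts equal to the epoch index."""
    return make_series(np.arange(1440.0))


@pytest.fixture(scope="session")
def small_study():
    """A small complete synthetic study with the default planted effect."""
    cfg = SyntheticConfig(
        seed=20240117,
        n_subjects=6,
        n_days=2,
        prompts_per_day=5,
        missing_prompt_prob=0.1,
    )
    return simulate_study(cfg)
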