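import numpy as np
import pandas as pd
import pytest

from pruralert import CohortConfig, simulate_cohort


def make_behavior(records):
    """Build a behavior table from (dog_id, date, scratch, lick, wear) tuples."""
    return pd.DataFrame(
        records,
        columns=["dog_id", "date", "scratch_seconds", "lick_minutes", "wear_fraction"],
    ).assign(date=lambda d: pd.to_datetime(d["date"]))


def constant_behavior(dog_id, start, n_days, scratch, lick, wear=1.0):
    dates = pd.date_range(start, periods=n_days, freq="D")
    return pd.DataFrame(
        {
            "dog_id": dog_id,
            "date": dates,
            "scratch_seconds": float(scratch),
            "lick_minutes": float(lick),
            "wear_fraction": float(wear),
        }
    )


@pytest.fixture(scope="session")
def small_config():
    """A 30-dog, 2x60-day cohort, quick enough for per-test simulation."""
    return CohortConfig(
        n_dogs=30,
        period_length_days=60,
        n_periods=2,
        flare_rate=1.5,
        baseline_visit_rate=1.0,
        response_prob_pre=0.05,
        response_prob_post=0.15,
        rng_seed=42,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return simulate_cohort(small_config)


@pytest.fixture(scope="session")
def medium_config():
    """200 dogs over the full two 292-day periods."""
    return CohortConfig(n_dogs=200, rng_seed=7)


@pytest.fixture(scope="session")
def medium_fit(medium_config):
    from pruralert import AlertResponseModel

    return AlertResponseModel.from_simulation(medium_config).fit()
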