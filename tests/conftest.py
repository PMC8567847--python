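import datetime as dt

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import baleendo as b

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def noise_free_scenario():
    """One term pregnancy, no assay noise, no spikes, clean isotope cycle."""
    return b.SimScenario(
        seed=3,
        assay_cv=0.0,
        spike_rate_per_cm=0.0,
        d15N_noise_sd=0.0,
        pregnancy_windows=(b.PregnancyWindow(dt.date(1999, 1, 15)),),
    )


@pytest.fixture
def sim_whale():
    def make(plate, truth):
        return b.WhaleRecord(
            plate.whale_id,
            sex="female",
            death_date=truth.scenario.death_date,
            date_found=truth.scenario.death_date,
        )

    return make


@pytest.fixture
def rng():
    return np.random.default_rng(0)
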