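import numpy as np
import pytest

from runload.load_metrics import session_summary
from runload.synthetic import (
    CohortParams,
    TreadmillParams,
    gen_outdoor_cohort,
    gen_treadmill_trial,
)


@pytest.fixture(scope="session")
def clean_trial():
    """A fully deterministic trial: no sensor noise, no mapping noise, no
    impact transient. Extraction must reproduce the truth identically."""
    params = TreadmillParams(
        speed_mps=3.33,
        n_steps=50,
        seed=7,
        imu_white_noise_g=0.0,
        acc_noise_sd_g=0.0,
        transient_amp_bw=0.0,
    )
    return params, gen_treadmill_trial(params)


@pytest.fixture(scope="session")
def default_trial():
    """A trial with the default noise and transient settings."""
    params = TreadmillParams(speed_mps=3.33, n_steps=90, seed=5)
    return params, gen_treadmill_trial(params)


@pytest.fixture(scope="session")
def cohort_seed1():
    """The default 96-runner cohort at seed 1, with session summaries."""
    records, truth = gen_outdoor_cohort(CohortParams(seed=1))
    summaries = [session_summary(r) for r in records]
    return records, truth, summaries


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
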