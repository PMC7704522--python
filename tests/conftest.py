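import matplotlib
import numpy as np
import pytest
from hypothesis import HealthCheck, settings

matplotlib.use("Agg")

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

import baroreflex as bx  # noqa: E402


@pytest.fixture(scope="session")
def noise_free_recording():
    """One noise-free subject-condition: 3 boli, exact coupling."""
    params = bx.ConditionParams(
        label="normoxia",
        sbp_baseline=133.0,
        hr_baseline=63.0,
        brs_true=20.0,
        dsbp_true=25.0,
        brs_bolus_sd=0.0,
        dsbp_bolus_sd=0.0,
        rri_noise_sd=0.0,
        sbp_noise_sd=0.0,
    )
    schedule = bx.BolusSchedule(n_boli=3, interval_s=240.0, first_bolus_s=120.0)
    beats, events = bx.simulate_beats(
        params, schedule, schedule.duration_needed_s(), seed=7
    )
    return params, schedule, beats, events


@pytest.fixture(scope="session")
def default_cohort_fit():
    """One seeded realization of the bundled nine-subject cohort, fitted."""
    study = bx.BaroreflexStudy.simulate(seed=11)
    return study, study.fit()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
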