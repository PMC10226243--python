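import numpy as np
import pytest
from hypothesis import settings

from survlock import (
    CohortSpec,
    SurvivalDataset,
    generate_cohort,
    lock_grid,
    mm_like_hazard_presets,
)

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def presets():
    return mm_like_hazard_presets()


@pytest.fixture
def hand_ds():
    """Three subjects: events at 1 and 3, censoring at 2 (classic by-hand KM)."""
    return SurvivalDataset(np.array([1.0, 2.0, 3.0]), np.array([1, 0, 1]))


@pytest.fixture(scope="session")
def piecewise_locked(presets):
    """A 300-subject piecewise-hazard cohort locked at 6 years: the
    workhorse medium-censoring dataset for fitting tests."""
    spec = CohortSpec(
        n_subjects=300,
        enroll_start=2002.72,
        enroll_end=2007.54,
        survival_model=presets["piecewise"],
        seed=7,
    )
    return lock_grid(generate_cohort(spec), [6.0])[0]


def sample_censored(truth, n, seed, cens_time=None, target_censoring=0.3):
    """Draw n survival times and administratively censor them at a fixed
    time chosen (from the truth) to censor roughly ``target_censoring``."""
    rng = np.random.default_rng(seed)
    t = truth.sample(rng, n)
    if cens_time is None:
        from scipy.optimize import brentq

        cens_time = brentq(
            lambda c: float(truth.survival(c)) - target_censoring, 1e-6, 1e4
        )
    time = np.minimum(t, cens_time)
    status = (t <= cens_time).astype(int)
    return SurvivalDataset(time, status)
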