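import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from neurovar.cohort import cohort_tracksets, delta_tracks
from neurovar.discrim import discriminability_scores
from neurovar.io import EpochSet
from neurovar.simulate import GeneratorConfig, generate_cohort

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_epochs(data, sfreq=1000.0, t0=-500.0, condition=None, subject_id="S000"):
    data = np.atleast_2d(np.asarray(data, dtype=float))
    times = t0 + np.arange(data.shape[1]) * 1000.0 / sfreq
    if condition is None:
        condition = ["low"] * data.shape[0]
    return EpochSet(
        subject_id=subject_id, sfreq=sfreq, times=times, data=data,
        condition=np.asarray(condition, dtype=object),
    )


@pytest.fixture(scope="session")
def small_cohort():
    """Compact planted-effect cohort shared by qualitative tests."""
    cfg = GeneratorConfig(n_subjects=24, n_trials_per_condition=10, seed=5)
    cohort, ratings, truth = generate_cohort(cfg)
    return cfg, cohort, ratings, truth


@pytest.fixture(scope="session")
def planted_cohort():
    """Full-size cohort at the default planted correlation (rho = 0.5)."""
    cfg = GeneratorConfig(n_subjects=200, seed=11)
    cohort, ratings, truth = generate_cohort(cfg)
    return cfg, cohort, ratings, truth


@pytest.fixture(scope="session")
def planted_tracks(planted_cohort):
    """ΔSD and ΔAmplitude tracks plus scores for the full-size cohort."""
    _, cohort, ratings, truth = planted_cohort
    var_d = delta_tracks(cohort_tracksets(cohort, "tempSD"))
    amp_d = delta_tracks(cohort_tracksets(cohort, "amplitude"))
    scores = discriminability_scores(ratings)
    return var_d, amp_d, scores, truth
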