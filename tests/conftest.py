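import numpy as np
import pytest

from neurofp import CohortConfig, TrialSet, generate_cohort


def random_trialset(rng, n_trials=6, n_regions=3, n_samples=50, labels=None):
    data = rng.standard_normal((n_trials, n_regions, n_samples))
    if labels is None:
        labels = [f"sub-{i % 2:03d}" for i in range(n_trials)]
    return TrialSet(data=data, labels=np.array(labels, dtype=object),
                    duration=n_samples / 100.0, sampling_rate=100.0)


@pytest.fixture(scope="session")
def small_cohort():
    """8 high-SNR subjects, 30 s sessions: enough for pipeline-level tests."""
    config = CohortConfig(
        n_subjects=8, duration_rs1=30.0, duration_rs2=30.0, duration_empty=30.0, seed=42
    )
    return generate_cohort(config)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
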