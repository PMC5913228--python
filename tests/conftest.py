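import numpy as np
import pytest

from transrev import task_design as td
from transrev.synthetic_data import SyntheticConfig, generate_cohort


@pytest.fixture(scope="session")
def schedule84():
    return td.generate_schedule(84, (9, 12), td.VREV, seed=1)


@pytest.fixture(scope="session")
def three_runs():
    return [
        td.generate_schedule(84, (9, 12), td.VREV if r % 2 == 0 else td.IREV, seed=10 + r)
        for r in range(3)
    ]


@pytest.fixture(scope="session")
def tiny_neural_cohort():
    """Two subjects with full BOLD on the default 16^3 grid (default conditions)."""
    cfg = SyntheticConfig(n_subjects=2, seed=11)
    subjects, manifest = generate_cohort(cfg)
    return cfg, subjects, manifest


@pytest.fixture(scope="session")
def noiseless_subject():
    """One subject generated without noise and with unit gain, for exact round-trips."""
    cfg = SyntheticConfig(n_subjects=1, seed=4, noise_sd=0.0, subject_gain_sd=0.0,
                          amp_noise_sd=0.0)
    subjects, _ = generate_cohort(cfg)
    return cfg, subjects[0]


@pytest.fixture
def rng():
    return np.random.default_rng(0)
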