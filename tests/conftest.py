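import logging

import numpy as np
import pytest

import brainstages as bs

logging.disable(logging.WARNING)


@pytest.fixture(scope="session")
def small_cohort():
    """Small two-structure cohort: one structure truly diverging, one null."""
    truths = [
        bs.TrajectoryTruth("thalamus", (0.124, 0.028, -0.00051), onset_age=60.0,
                           deviation_rate=0.15, noise_sd=0.8,
                           lr_split_fraction=0.5, norm_mean=1.0, norm_sd=0.1),
        bs.TrajectoryTruth("brainstem", (0.124, 0.028, -0.00051), onset_age=None,
                           deviation_rate=0.0, noise_sd=0.8,
                           lr_split_fraction=None, norm_mean=1.55, norm_sd=0.15),
    ]
    specs = bs.default_control_specs(800) + [bs.default_case_spec(60)]
    subjects, truth = bs.generate_cohort(specs, truths, seed=2024)
    return subjects, truth, truths


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
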