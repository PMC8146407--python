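"""Shared fixtures: schedules and synthetic subjects at test-friendly sizes.

The ``small_design`` trims the session to 4 mini-blocks (96 trials) so
continuous-signal tests stay fast; full-session fixtures are reserved
for the acceptance suite.
"""

import numpy as np
import pytest

from flankerlab import paradigm, synthetic


@pytest.fixture(scope="session")
def default_schedule():
    return paradigm.generate_sequence(seed=7)


@pytest.fixture(scope="session")
def small_design():
    return paradigm.SequenceDesign(n_blocks=4, n_training_blocks=0)


@pytest.fixture(scope="session")
def small_schedule(small_design):
    return paradigm.generate_sequence(small_design, seed=11)


@pytest.fixture(scope="session")
def quiet_noise():
    """No background, no blinks, no artifacts: the noiseless limit."""
    return synthetic.NoiseConfig(
        pink_sd_uv=0.0, eog_pink_sd_uv=0.0, alpha_amp_uv=0.0,
        blink_rate_per_min=0.0, artifact_rate=0.0,
        fnirs_cardiac_amp_od=0.0, fnirs_mayer_amp_od=0.0,
        fnirs_drift_od_per_min=0.0, fnirs_white_sd_od=0.0)


@pytest.fixture(scope="session")
def fixed_effects():
    """No between-subject variability: templates realized exactly."""
    return synthetic.EffectConfig(
        amp_scale_sd=0.0, latency_jitter_sd_ms=0.0, rt_subject_sd_ms=0.0,
        rt_delta_sd_ms=0.0, accuracy_logit_sd=0.0, fnirs_beta_scale_sd=0.0)


@pytest.fixture(scope="session")
def noiseless_subject(small_schedule, quiet_noise, fixed_effects):
    ds, truth = synthetic.simulate_subject(
        small_schedule, fixed_effects, quiet_noise, seed=3)
    return ds, truth


@pytest.fixture(scope="session")
def noisy_subject(small_schedule):
    ds, truth = synthetic.simulate_subject(small_schedule, seed=5)
    return ds, truth
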