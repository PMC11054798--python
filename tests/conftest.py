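import numpy as np
import pytest

from gaitphase.synthetic import (
    GaitCondition,
    SubjectParams,
    default_calibrations,
    generate_dataset,
    simulate_session,
)


@pytest.fixture(scope="session")
def tiny_dataset():
    """Three short synthetic sessions sharing the full 8-condition protocol."""
    return generate_dataset(3, "paper", master_seed=123, duration_scale=0.05)


@pytest.fixture(scope="session")
def quiet_session():
    """One noise-free constant-speed session for analytic checks."""
    subject = SubjectParams(noise_std_accel=0.0, noise_std_gyro=0.0, rng_seed=5)
    cond = GaitCondition(name="normal_stride", duration=20.0,
                         knots=(0.0, 1.0), v_left=(0.8, 0.8),
                         v_right=(0.8, 0.8))
    return simulate_session([cond], subject)


@pytest.fixture(scope="session")
def calibs():
    return default_calibrations()
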