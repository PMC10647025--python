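import dataclasses

import numpy as np
import pytest

from ribecho.sim import (CohortConfig, DeviceConfig, Participant,
                         synth_dataset)


def make_participant(rib_depth: float = 2.0, bmi: float = 25.0,
                     height: float = 172.0, pid: str = "P01",
                     sex: str = "M") -> Participant:
    """Hand-built participant with controllable ground truth."""
    return Participant(
        id=pid, sex=sex, age=40.0, height=height,
        weight=bmi * (height / 100.0) ** 2, bmi=bmi,
        circumference_waist=90.0, circumference_navel=95.0,
        circumference_sternum=98.0, length_navel_sternum=22.0,
        length_navel_chin=44.0, length_hip_armpit=39.0,
        cohort="low_bmi" if bmi < 30 else "high_bmi",
        rib_depth=rib_depth, intercostal_width=2.8,
    )


@pytest.fixture(scope="session")
def device():
    return DeviceConfig()


@pytest.fixture(scope="session")
def quiet_device():
    """Device with the excitation artifact disabled (echo-only traces)."""
    return DeviceConfig(artifact_amplitude=0.0)


@pytest.fixture(scope="session")
def noiseless_config():
    return dataclasses.replace(CohortConfig(), noise_sd=0.0)


@pytest.fixture(scope="session")
def small_config():
    """Reduced study: 6 low-BMI + 4 high-BMI participants, 3 reps."""
    return dataclasses.replace(CohortConfig(), n_low_bmi=6, n_high_bmi=4,
                               reps_per_location=3, seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return synth_dataset(small_config)


@pytest.fixture(scope="session")
def study_dataset():
    """Full-scale default study: 20 participants, 1000 traces."""
    return synth_dataset(CohortConfig())


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
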