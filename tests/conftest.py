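import numpy as np
import pytest

from gaitspeed.synth import NoiseModel, StrideKinematicsSpec, synth_walk


@pytest.fixture
def noiseless():
    return NoiseModel(accel_sigma=0.0, gyro_sigma=0.0, gyro_bias=0.0)


@pytest.fixture
def uniform_walk(noiseless):
    """A noiseless 18-stride straight walk at 1.0 m/s (1.1 s cycles)."""
    specs = [StrideKinematicsSpec(stride_length=1.1, duration=1.1, noise=noiseless)
             for _ in range(18)]
    return synth_walk([specs], noise=noiseless, seed=0)


@pytest.fixture
def noisy_walk():
    """A 12-stride walk under the default MEMS noise model."""
    specs = [StrideKinematicsSpec(stride_length=1.2, duration=1.1)
             for _ in range(12)]
    return synth_walk([specs], seed=11)


def make_still_recording(n=800, fs=128.0, accel_sigma=0.05, gyro_sigma=0.01, seed=0):
    """A stationary recording: gravity plus sensor noise."""
    from gaitspeed.constants import G
    from gaitspeed.io import IMURecording

    rng = np.random.default_rng(seed)
    accel = np.zeros((n, 3))
    accel[:, 2] = G
    accel += rng.normal(0, accel_sigma, (n, 3))
    gyro = rng.normal(0, gyro_sigma, (n, 3))
    return IMURecording(t=np.arange(n) / fs, accel=accel, gyro=gyro, fs=fs)
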