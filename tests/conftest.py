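import numpy as np
import pytest

from headgest import (
    DetectionConfig,
    GeneratorConfig,
    ImuSequence,
    PreprocessConfig,
)


@pytest.fixture
def pp() -> PreprocessConfig:
    return PreprocessConfig()


@pytest.fixture
def det() -> DetectionConfig:
    return DetectionConfig()


@pytest.fixture
def gen() -> GeneratorConfig:
    return GeneratorConfig()


@pytest.fixture
def clean_gen() -> GeneratorConfig:
    """Generator with every noise source and the time-warp switched off."""
    return GeneratorConfig(
        gyro_noise_sd=0.0, accel_noise_sd=0.0, impulse_prob=0.0, warp_strength=0.0
    )


def stream_from_gz(gz: np.ndarray, fs: float = 100.0) -> ImuSequence:
    """Wrap a bare z-gyro series into a 6-channel sequence (other channels 0)."""
    data = np.zeros((len(gz), 6))
    data[:, 5] = gz
    return ImuSequence(data, fs=fs)


def random_multichannel(rng: np.random.Generator, n: int, c: int = 6) -> np.ndarray:
    return rng.normal(0.0, 1.0, size=(n, c))
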