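import numpy as np
import pytest

from atckit.acoustics import BubbleGeom, PulseTrain
from atckit.synthetic import SceneSpec, default_calibration


@pytest.fixture(scope="session")
def train_5pct() -> PulseTrain:
    return PulseTrain.constant(prf=1.0, duty=0.05, n_pulses=5,
                               pressure=0.035e6)


@pytest.fixture(scope="session")
def train_50pct() -> PulseTrain:
    return PulseTrain.constant(prf=1.0, duty=0.50, n_pulses=5,
                               pressure=0.035e6)


@pytest.fixture(scope="session")
def kv_5pct():
    return default_calibration(0.05)


@pytest.fixture(scope="session")
def kv_50pct():
    return default_calibration(0.50)


@pytest.fixture(scope="session")
def two_bubble_scene(kv_50pct) -> SceneSpec:
    """Noise-free two-bubble scene rendered at 100 fps for tracking tests."""
    return SceneSpec(
        bubbles=[BubbleGeom("b0", (8.0, 12.0), 2.0),
                 BubbleGeom("b1", (8.0, 22.0), 2.0)],
        kv_params=kv_50pct, noise_sd=0.0, frame_rate=100.0,
        fov_px=(96, 96), rng_seed=7)
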