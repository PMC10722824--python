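import numpy as np
import pytest

from gazevam.fixtures import (
    GazeSimConfig,
    Stimulus,
    StimulusConfig,
    generate_stimulus,
    simulate_gaze,
)
from gazevam.preprocess import aggregate_frames


@pytest.fixture(scope="session")
def small_stimulus() -> Stimulus:
    """3-second default-resolution stimulus shared across tests."""
    return generate_stimulus(StimulusConfig(duration_s=3.0), seed=11)


@pytest.fixture(scope="session")
def small_recordings(small_stimulus):
    cfg = GazeSimConfig(n_td=6, n_asd=6)
    return simulate_gaze(small_stimulus, cfg, seed=12)


@pytest.fixture(scope="session")
def small_groups(small_stimulus):
    return aggregate_frames(small_stimulus, threshold=0.33)


def gray_stimulus(levels, fps: float = 30.0) -> Stimulus:
    """Uniform-gray frame sequence with prescribed intensities.

    Inter-frame motion between frames i and i+1 is exactly
    |levels[i] - levels[i+1]|, which lets tests prescribe arbitrary motion
    profiles.
    """
    levels = np.asarray(levels, dtype=np.float32)
    frames = np.ones((len(levels), 8, 8, 3), dtype=np.float32) * levels[:, None, None, None]
    return Stimulus(frames=frames, fps=fps)
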