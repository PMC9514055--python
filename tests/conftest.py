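import numpy as np
import pytest

from gazecam import (DisplayGeometry, GazeModelParams, StimulusSpec,
                     generate_stimulus_set)


@pytest.fixture(scope="session")
def small_stimuli():
    """A small 4-category stimulus set at 64 px (2 animate, 2 inanimate)."""
    spec = StimulusSpec(n_categories=4, n_images_per_category=6, image_size=64,
                        face_probability=1.0, seed=11)
    return generate_stimulus_set(spec)


@pytest.fixture(scope="session")
def geometry():
    return DisplayGeometry.centered(64)


@pytest.fixture()
def gaze_params():
    return GazeModelParams(seed=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
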