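import numpy as np
import pytest

import neurotune as nt
from neurotune.landscapes import UnimodalLandscapePnds


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def space():
    return nt.ndsep_space()


@pytest.fixture(scope="session")
def landscape(space):
    return UnimodalLandscapePnds(space)


@pytest.fixture(scope="session")
def tiny_scene():
    """A small noisy recording with exact ground truth, for fast
    end-to-end tests."""
    spec = nt.SceneSpec(height=40, width=40, n_neurons=5, n_frames=60,
                        radius_range=(2.5, 4.0), seed=3)
    return nt.generate_dataset(spec)
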