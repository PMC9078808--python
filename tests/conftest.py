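import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from ceustrack import SceneConfig, generate_sequence


@pytest.fixture(scope="session")
def default_scene():
    """The standard 50-frame synthetic benchmark sequence (default config)."""
    frames, truth = generate_sequence(SceneConfig(seed=0))
    return frames, truth


@pytest.fixture(scope="session")
def short_scene():
    """A quick 12-frame sequence for unit-level checks."""
    frames, truth = generate_sequence(SceneConfig(n_frames=12, seed=3))
    return frames, truth


@pytest.fixture(scope="session")
def smooth_texture():
    """Band-limited random texture for flow shift oracles (96x96, 8-bit range)."""
    rng = np.random.default_rng(42)
    tex = gaussian_filter(rng.standard_normal((96, 96)), 2.0)
    return 128.0 + 60.0 * tex / tex.std()
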