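import numpy as np
import pytest

from wcesim.io import save_image
from wcesim.synth import SynthConfig, generate_image


@pytest.fixture
def rng():
    return np.random.default_rng(20240311)


@pytest.fixture
def random_image(rng):
    """A 32x32 random RGB image with all intensities >= 1 (invertible range)."""
    return rng.integers(1, 256, size=(32, 32, 3)).astype(np.uint8)


@pytest.fixture
def synth_config():
    """Small frames keep pixel work cheap in unit tests."""
    return SynthConfig(image_size=48)


@pytest.fixture
def wired_image(synth_config):
    return generate_image("Angulus", "wired", synth_config, seed=1)


@pytest.fixture
def small_tree(tmp_path, rng):
    """A 3-class image tree with 4/3/2 images for scan/transfer tests."""
    root = tmp_path / "tree"
    counts = {"alpha": 4, "beta": 3, "gamma": 2}
    for cls, n in counts.items():
        for i in range(n):
            img = rng.integers(0, 256, size=(16, 16, 3)).astype(np.uint8)
            save_image(img, root / cls / f"{cls}_{i}.png")
    return root, counts
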