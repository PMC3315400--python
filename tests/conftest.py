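import numpy as np
import pytest
from hypothesis import settings

from histotex import lbp, synthetic

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def texture_grays():
    """Small grayscale textures of both classes, 4 per class, 120 px."""
    out = {"blob": [], "fiber": []}
    for kind in out:
        for i in range(4):
            spec = synthetic.SyntheticSpec(
                kind, size=120, seed=1000 + i,
                fiber_orientation=float(37 * i % 180))
            out[kind].append(synthetic.generate_gray(spec))
    return out


@pytest.fixture(scope="session")
def quantizers(texture_grays):
    """Default (8,1) and (16,2) VAR quantizers trained on the fixtures."""
    images = texture_grays["blob"] + texture_grays["fiber"]
    return lbp.train_default_quantizers(images)


@pytest.fixture(scope="session")
def small_dataset():
    """Seeded synthetic dataset: 5 train / 3 val / 2 test images per class."""
    return synthetic.generate_dataset(10, ratios=(0.5, 0.25, 0.25),
                                      seed=7, size=160)
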