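import numpy as np
import pandas as pd
import pytest

from artstats import features as features_mod
from artstats import synth
from artstats.phog import RasterImage


@pytest.fixture(scope="session")
def default_collection():
    """The default 150-image synthetic collection and its feature table.

    Session-scoped: feature extraction over 150 images is the most
    expensive fixture in the suite and several tests share it.
    """
    images, truth = synth.generate_image_collection(150, seed=11)
    feats = features_mod.compute_all_features(images)
    return images, truth, feats


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def iid_features():
    """Synthetic standardized feature table (independent columns)."""
    gen = np.random.default_rng(99)
    cols = ["self_similarity", "complexity", "anisotropy", "birkhoff",
            "hsv_hue", "hsv_saturation", "hsv_value", "lab_l", "lab_b"]
    return pd.DataFrame(
        gen.standard_normal((150, len(cols))),
        index=[f"img{i:03d}" for i in range(150)],
        columns=cols,
    )


def make_gray_image(gray: np.ndarray, image_id: str = "test") -> RasterImage:
    g = np.asarray(gray, dtype=np.uint8)
    return RasterImage(np.repeat(g[:, :, None], 3, axis=2), id=image_id)
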