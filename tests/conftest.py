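import numpy as np
import pytest

from acnekit import synthetic as syn
from acnekit.quality import fit_sharpness_model, sharpness_features
from acnekit.records import ImageRecord


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def scene():
    """One deterministic scene with every lesion class present."""
    spec = syn.SceneSpec(seed=7, counts={"comedone": 2, "papule": 1,
                                         "pustule": 1, "nodule": 1,
                                         "cyst": 1, "scar": 1})
    return syn.render_scene(spec)


def gray_image(value: int, size: int = 32) -> ImageRecord:
    px = np.full((size, size, 3), value, dtype=np.uint8)
    return ImageRecord(id=f"gray{value}", pixels=px)


@pytest.fixture(scope="session")
def fixture_pairs():
    """100 (sharp, blurred) scene pairs, seeded."""
    pairs = []
    for i in range(100):
        spec = syn.SceneSpec(seed=9000 + i, counts={"comedone": 2, "papule": 1,
                                                    "pustule": 0, "nodule": 0,
                                                    "cyst": 0, "scar": 1})
        rec, _ = syn.render_scene(spec)
        pairs.append((rec, syn.degrade(rec, "blur", sigma=2.0)))
    return pairs


@pytest.fixture(scope="session")
def sharpness_model(fixture_pairs):
    """Logistic sharpness model fitted on the first 50 fixture pairs."""
    feats, labels = [], []
    for sharp, blurred in fixture_pairs[:50]:
        feats.append(sharpness_features(sharp))
        labels.append(1)
        feats.append(sharpness_features(blurred))
        labels.append(0)
    return fit_sharpness_model(feats, labels)
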