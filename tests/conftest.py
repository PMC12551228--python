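import numpy as np
import pytest

from painseeker.model import FacialImage, PainLabel, PainSeekerModel
from painseeker.synthetic import SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """3 subjects, 18 images, 32×32 — enough for protocol and IO tests."""
    cfg = SyntheticConfig(
        n_subjects=3,
        counts_per_subject={"s1": (3, 3), "s2": (3, 3), "s3": (2, 4)},
        image_size=32, seed=7)
    return generate_dataset(cfg)


@pytest.fixture()
def tiny_model():
    return PainSeekerModel(backbone="tiny", input_size=32, n_classes=2,
                           seed=3, width=8, d_x=8)


def make_image(pixels, subject="s1", ordinal=0, image_id="img0"):
    return FacialImage(pixels=pixels, subject_id=subject,
                       label=PainLabel(ordinal), image_id=image_id)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
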