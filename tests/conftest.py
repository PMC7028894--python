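import numpy as np
import pytest

from thermostage.pipeline import preprocess_images
from thermostage.synthetic import SynthConfig, generate_images


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small labelled synthetic set: (raws, masks, stages). Counts 5/7/6/5."""
    raws, masks = generate_images({0: 5, 1: 7, 2: 6, 3: 5}, SynthConfig(), seed=42)
    stages = np.array([r.stage for r in raws])
    return raws, masks, stages


@pytest.fixture(scope="session")
def tiny_rois(tiny_dataset):
    """ROI images of the tiny dataset (exercises the full preprocessing chain)."""
    raws, _, stages = tiny_dataset
    return preprocess_images(raws), stages


@pytest.fixture()
def one_thermogram():
    from thermostage.synthetic import generate_thermogram

    return generate_thermogram(2, SynthConfig(), seed=7)
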