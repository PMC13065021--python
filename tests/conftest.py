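import numpy as np
import pytest

from wormgrowth import segmentation, synthetic


@pytest.fixture(scope="session")
def noiseless_render():
    """One noiseless, unblurred rendered worm with its true mask."""
    rng = np.random.default_rng(7)
    img, mask, midline = synthetic.render_worm_frame(
        1.2e5, 100.0, (240, 240), 2.5, 20.0, 0.0, rng, blur_sigma=0.0
    )
    return img.astype(float), mask, midline


@pytest.fixture(scope="session")
def qc_features():
    """Training and held-out feature tables from the synthetic QC generator."""
    def table(ts):
        x = np.array([segmentation.features_from_mask(m).values for m in ts.masks])
        return x, ts.labels, ts.classes

    train = synthetic.make_qc_training_set(40, 40, seed=11)
    test = synthetic.make_qc_training_set(30, 30, seed=12)
    return table(train), table(test)


@pytest.fixture(scope="session")
def trained_qc(qc_features):
    (xtr, ytr, _), _ = qc_features
    return segmentation.train_qc_classifier(xtr, ytr, seed=5)
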