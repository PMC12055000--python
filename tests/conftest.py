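import numpy as np
import pytest

import adpt


@pytest.fixture
def skeleton():
    return adpt.MOUSE5


@pytest.fixture
def config():
    """Desk-scale configuration: 64x64 images, stride 8, sharp targets."""
    return adpt.Config(
        sigma=1.0,
        locref_radius=1.5,
        n_identities=1,
        nms_radius=2,
        identity_radius=1,
    )


@pytest.fixture
def pair_config(config):
    return config.replace(n_identities=2)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_keypoint_frame(rng, skeleton, size=64, n_instances=1, margin=4.0):
    """A LabeledFrame with random in-bounds keypoints (blank image)."""
    instances = []
    for ident in range(1, n_instances + 1):
        kp = rng.uniform(margin, size - 1 - margin, size=(skeleton.n_keypoints, 2))
        instances.append(
            adpt.Instance(ident, kp, np.ones(skeleton.n_keypoints, dtype=bool))
        )
    image = np.zeros((size, size, 3), dtype=np.uint8)
    return adpt.LabeledFrame(image, instances)
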