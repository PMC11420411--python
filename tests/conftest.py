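import numpy as np
import pytest

from flowdenoise import GeometryConfig
from flowdenoise.backbone import BackboneConfig


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def _binary_images(n_side: int) -> list[np.ndarray]:
    """Small piecewise-constant images in roughly unit scale."""
    x, y = np.meshgrid(np.linspace(-1, 1, n_side), np.linspace(-1, 1, n_side))
    return [
        np.where(x**2 + y**2 < 0.5, 0.5, -0.5),
        np.where((np.abs(x) < 0.4) & (np.abs(y) < 0.6), 0.7, -0.3),
        np.where(x > 0, 0.3, -0.7),
        np.where(x + y > 0.2, 0.6, -0.4),
    ]


@pytest.fixture(scope="session")
def toy_images_8():
    return _binary_images(8)


@pytest.fixture(scope="session")
def toy_images_16():
    return _binary_images(16)


@pytest.fixture
def geom_small():
    return GeometryConfig(data_dim=64, aug_dim=64)


@pytest.fixture
def tiny_backbone_config():
    return BackboneConfig(
        base_channels=8, channel_multipliers=(1, 2), emb_channels=16, n_freqs=4
    )
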