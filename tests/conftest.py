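import numpy as np
import pytest

from mitoquant.detect import ThresholdConfig
from mitoquant.images import ChannelImage
from mitoquant.synthetic import CountDistribution, NoiseModel, SceneSpec


@pytest.fixture
def default_cfg() -> ThresholdConfig:
    return ThresholdConfig()


@pytest.fixture
def clean_spec() -> SceneSpec:
    """Small noise-free, blur-free scene: puncta are exact stamped disks."""
    return SceneSpec(
        image_shape=(192, 192),
        n_cells=4,
        cell_radius_px=24,
        cytosol_intensity=0.0,
        psf_sigma=0.0,
        noise=NoiseModel(),
        seed=11,
    )


@pytest.fixture
def default_spec() -> SceneSpec:
    """Default rendering (PSF on, noise off)."""
    return SceneSpec(seed=7)


def make_channel(data, pixel_size=0.2, role="red") -> ChannelImage:
    return ChannelImage(np.asarray(data, dtype=float), pixel_size, role)


@pytest.fixture
def autoqc_spec() -> SceneSpec:
    return SceneSpec(
        n_mitolysosomes_per_cell=CountDistribution(0, 0),
        n_autophagosomes_per_cell=CountDistribution(3),
        n_autolysosomes_per_cell=CountDistribution(3),
        mito_overlap_fraction=0.3,
        seed=5,
    )
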