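import numpy as np
import pytest

from symslice.phantoms import PhantomSpec, generate_cohort, generate_phantom
from symslice.pipeline import PipelineConfig
from symslice.volume import VolumeGrid, resample_isotropic


@pytest.fixture(scope="session")
def pipeline_config() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture(scope="session")
def clean_head():
    """Noise-free, jitter-free head phantom with its ground-truth plane."""
    vol, plane = generate_phantom(PhantomSpec(class_id="head", noise_sd=0.0, asymmetry_jitter=0.0, seed=7))
    return vol, plane


@pytest.fixture(scope="session")
def iso_head(clean_head):
    vol, plane = clean_head
    return resample_isotropic(vol), plane


@pytest.fixture(scope="session")
def study_cohort():
    """20 phantoms (5 per class) at the study's default noise and 0.5-voxel jitter."""
    return generate_cohort(5, PhantomSpec(noise_sd=5.0, asymmetry_jitter=0.5), seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def random_cloud(rng):
    from symslice.segmentation import PointCloud

    return PointCloud(rng.uniform(0, 40, size=(400, 3)))


def make_volume(data, spacing=(1.0, 1.0, 1.0)) -> VolumeGrid:
    return VolumeGrid(np.asarray(data, dtype=float), spacing)
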