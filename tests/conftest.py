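import numpy as np
import pytest

from dbmorph.core import DeformationField, GrayImage
from dbmorph.phantom import PhantomSpec, generate_cohort, make_reference


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_spec():
    """A fast 64x64 phantom spec used across tests."""
    return PhantomSpec(image_size=64, n_control=4, n_diseased=4,
                       lesion_centers=((26.0, 38.0),), seed=42)


@pytest.fixture(scope="session")
def reference(small_spec):
    return make_reference(small_spec)


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    return generate_cohort(small_spec)


@pytest.fixture
def smooth_field(rng):
    """A small smooth deformation field on a 40x40 grid."""
    from scipy import ndimage

    raw = np.stack(
        [ndimage.gaussian_filter(rng.standard_normal((40, 40)), 6.0)
         for _ in range(2)], axis=-1,
    )
    peak = np.sqrt((raw**2).sum(-1)).max()
    return DeformationField(raw * (1.5 / peak))


def make_gray(arr):
    return GrayImage(np.asarray(arr, dtype=float))
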