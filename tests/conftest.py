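import numpy as np
import pytest

from gliorad.preproc import Image3D, NormalizedImage
from gliorad.synthetic import CohortConfig, generate_case
from gliorad.voi import VOI


@pytest.fixture(scope="session")
def small_config():
    return CohortConfig(n_cases=4, grid_shape=(48, 48, 48), seed=7)


@pytest.fixture(scope="session")
def one_case(small_config):
    return generate_case(small_config, 0)


@pytest.fixture(scope="session")
def preprocessed_case(one_case):
    from gliorad.pipeline import preprocess_case
    return preprocess_case(one_case)


def make_norm(levels, validity=None, spacing=(1, 1, 1)):
    levels = np.asarray(levels)
    if validity is None:
        validity = np.ones(levels.shape, bool)
    return NormalizedImage(levels, validity, "T1",
                           (100.0, float(levels.max()), float(levels.min())),
                           np.asarray(spacing, float), np.eye(4))


def make_voi(mask, role="core", spacing=(1, 1, 1)):
    return VOI(np.asarray(mask, bool), role, "gd",
               np.asarray(spacing, float), np.eye(4))


def make_image(voxels, spacing=(1, 1, 1), tag="T1"):
    return Image3D(np.asarray(voxels, float), np.asarray(spacing, float),
                   np.eye(4), tag)


@pytest.fixture
def helpers():
    class H:
        norm = staticmethod(make_norm)
        voi = staticmethod(make_voi)
        image = staticmethod(make_image)
    return H
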