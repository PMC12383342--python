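"""Shared fixtures: small synthetic cohorts and a single extracted phantom.

Heavy artifacts (cohorts, one full feature extraction) are session-scoped so
the numba kernels compile once and every test reuses the same objects.
"""

import numpy as np
import pytest

from habitatmil.features import extract_all
from habitatmil.habitat import HabitatConfig, delineate_habitats
from habitatmil.preprocess import CTVolume, MaskVolume, PreprocessConfig, clip_hu
from habitatmil.synthetic import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def pre_cfg():
    return PreprocessConfig()


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(CohortConfig(n_patients=10, seed=7))


@pytest.fixture(scope="session")
def phantom_patient(small_cohort):
    return small_cohort[0]


@pytest.fixture(scope="session")
def phantom_habitat(phantom_patient, pre_cfg):
    vol = clip_hu(phantom_patient.ct, pre_cfg)
    return delineate_habitats(vol, phantom_patient.mask, HabitatConfig(seed=0), pre_cfg)


@pytest.fixture(scope="session")
def phantom_features(phantom_patient, pre_cfg):
    """Full 1834-feature vector of one phantom's whole ROI."""
    vol = clip_hu(phantom_patient.ct, pre_cfg)
    return extract_all(vol, phantom_patient.mask, pre_cfg)


@pytest.fixture()
def sphere_pair():
    """A 15 mm digital sphere with a smooth background, 1 mm spacing."""
    shape = (40, 40, 40)
    g = np.indices(shape)
    c = np.array(shape)[:, None, None, None] / 2.0
    r = np.sqrt(((g - c) ** 2).sum(axis=0))
    mask = (r <= 15).astype(np.uint8)
    vol = CTVolume(50.0 + 0.5 * g[0].astype(float))
    return vol, MaskVolume(mask)
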