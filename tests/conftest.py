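"""Shared fixtures: one small synthetic cohort reused across test modules."""

import numpy as np
import pytest

from densvar import mapping_analysis as ma
from densvar import preprocessing as pp
from densvar import synthetic_data as sd


@pytest.fixture(scope="session")
def small_cohort():
    return sd.generate_cohort(
        sd.CohortConfig(n_subjects=40, image_size=32, seed=7))


@pytest.fixture(scope="session")
def reader_pool():
    return sd.make_reader_pool(m=5, seed=11)


@pytest.fixture(scope="session")
def label_table(small_cohort, reader_pool):
    return sd.assign_reader_pairs(small_cohort, reader_pool, seed=13)


@pytest.fixture(scope="session")
def metadata(small_cohort):
    return small_cohort.metadata()


@pytest.fixture(scope="session")
def preprocessed_images(small_cohort):
    cfg = pp.PreprocessConfig(target_size=32)
    return [(im.image_id, pp.preprocess_image(im, cfg))
            for im in small_cohort.images]


@pytest.fixture(scope="session")
def features(preprocessed_images):
    return ma.extract_features(preprocessed_images)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
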