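import numpy as np
import pytest

from ectpredict import CohortConfig, generate_cohort
from ectpredict.cohort import clinical_table
from ectpredict.features import assemble_feature_matrix
from ectpredict.outcomes import label_cohort


@pytest.fixture(scope="session")
def small_config():
    # 20 subjects keeps unit tests fast; designated blocks all present
    return CohortConfig(
        n_subjects=20, n_rois=16, n_rsns=4, collinear_block_size=2,
        n_constant_features=1, seed=42)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


@pytest.fixture(scope="session")
def small_features(small_cohort):
    return assemble_feature_matrix(small_cohort)


@pytest.fixture(scope="session")
def small_labels(small_cohort):
    return label_cohort(clinical_table(small_cohort))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
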