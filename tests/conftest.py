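import numpy as np
import pytest
from sklearn.datasets import make_blobs

from tsdpso.preprocess import clean_table
from tsdpso.synthetic import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def separable_blobs():
    """Two far-apart Gaussian blobs: any sensible RBF-SVM scores 0 error."""
    x, y = make_blobs(
        n_samples=200, centers=[[0.0] * 4, [10.0] * 4], cluster_std=0.5, random_state=2
    )
    return x, y


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(CohortSpec(n_per_class=120, delta=2.0, seed=7))


@pytest.fixture(scope="session")
def defect_free_base():
    """A cohort pre-cleaned at a stricter z-cut so that a later |z| > 3 pass
    only reacts to defects planted afterwards."""
    raw = generate_cohort(CohortSpec(n_per_class=150, delta=1.0, seed=3))
    table, _ = clean_table(raw, z_threshold=2.5)
    return table.to_dataframe().reset_index(drop=True)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
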