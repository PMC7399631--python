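import numpy as np
import pytest

import triplenet as tn


@pytest.fixture(scope="session")
def default_cohort():
    """One seeded default cohort: 32 patients + 37 controls, 7 x 200 series."""
    return tn.generate_cohort(tn.CohortConfig(seed=20240001))


@pytest.fixture(scope="session")
def cohort_matrices(default_cohort):
    subjects, _ = default_cohort
    matrices = [tn.connectivity_matrix(s) for s in subjects]
    labels = [s.group for s in subjects]
    return matrices, labels


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
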