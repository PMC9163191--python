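import numpy as np
import pandas as pd
import pytest

import actidep as a

#: true-effect cohort conditions shared by recovery tests: coefficients solved
#: to realize standardized effects ~0.6/0.4 at MADRS noise sd 2
TRUE_COEFS = {"alpha_full": -42.2, "IS5": 24.5}
COHORT_KW = dict(coefficients=TRUE_COEFS, intercept=70.0, noise_sd=2.0,
                 madrs_range=(10, 50))


@pytest.fixture(scope="session")
def cohort_pair():
    """Seeded 12+12 train/test cohorts with two known true predictors."""
    train = a.make_cohort(a.CohortSpec(n_subjects=12, seed=11, **COHORT_KW))
    test = a.make_cohort(a.CohortSpec(n_subjects=12, seed=12, **COHORT_KW))
    return train, test


@pytest.fixture(scope="session")
def brute_results(cohort_pair):
    """Brute-force internal-filter survivors on the training cohort."""
    train, _ = cohort_pair
    survivors, total = a.brute_force(train)
    return survivors, total


@pytest.fixture(scope="session")
def default_recording():
    return a.make_activity_recording(a.SimParams(seed=7))


def make_series(counts, start="2024-01-01 00:00", mask=None):
    return a.EpochSeries(start_time=pd.Timestamp(start),
                         counts=np.asarray(counts, dtype=float),
                         gap_mask=mask)
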