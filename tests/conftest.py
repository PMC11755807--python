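import numpy as np
import pandas as pd
import pytest

from piwiflow.synthcohort import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small cohort reused by read-level and totals tests."""
    cfg = CohortConfig(
        seed=11, n_ctr=4, n_lr=6, n_hr=6, n_te=40, n_pirna=30, n_pcg=60,
        n_mirna=40, pirna_duplicate_frac=0.1,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def default_cohort():
    """Full-size cohort under the default study conditions."""
    return generate_cohort(CohortConfig(seed=5))


@pytest.fixture()
def rng():
    return np.random.default_rng(123)


def nb_counts(rng, mu, dispersion, size):
    """NB draws with variance mu + dispersion * mu^2 (test-side helper)."""
    if dispersion == 0:
        return rng.poisson(mu, size=size)
    r = 1.0 / dispersion
    return rng.negative_binomial(r, r / (r + mu), size=size)
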