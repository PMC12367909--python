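import numpy as np
import pytest

from radsurv.synthcohort import CohortConfig, generate_cohort, cohort_frame


@pytest.fixture(scope="session")
def small_cohort():
    """A 60-patient cohort at small image size, shared across tests."""
    cfg = CohortConfig(n_patients=60, seed=11, grid_shape=(16, 16, 16))
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_table(small_cohort):
    return cohort_frame(small_cohort)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260926)


def random_survival(rng, n=80, beta=None, p=3, censor_scale=8.0):
    """Simple exponential survival data with optional linear signal."""
    if beta is not None:
        beta = np.asarray(beta, float)
        p = len(beta)
    else:
        beta = np.zeros(p)
    X = rng.standard_normal((n, p))
    eta = X @ beta
    t = rng.exponential(1.0 / (0.12 * np.exp(eta)))
    c = rng.uniform(0.5, censor_scale, n)
    time = np.minimum(t, c)
    event = (t <= c).astype(int)
    return X, time, event
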