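import numpy as np
import pytest

from neurodi.ensemble import TrialEnsemble
from neurodi.estimators import EstimatorConfig


@pytest.fixture(scope="session")
def gaussian_cfg():
    return EstimatorConfig(method="gaussian")


@pytest.fixture(scope="session")
def adaptive_cfg():
    return EstimatorConfig(method="adaptive_partition")


@pytest.fixture(scope="session")
def histogram_cfg():
    return EstimatorConfig(method="histogram")


def make_lag1_pair(a, b, c, n_trials, n_time, seed, sigma_x=1.0, sigma_y=1.0):
    """Unidirectional lag-1 Gaussian pair with zero pre-history, matching
    neurodi.simulators.linear_pair_covariance exactly."""
    rng = np.random.default_rng(seed)
    x = np.zeros((n_trials, n_time))
    y = np.zeros((n_trials, n_time))
    for n in range(n_time):
        xprev = x[:, n - 1] if n > 0 else 0.0
        yprev = y[:, n - 1] if n > 0 else 0.0
        x[:, n] = a * xprev + sigma_x * rng.standard_normal(n_trials)
        y[:, n] = b * yprev + c * xprev + sigma_y * rng.standard_normal(n_trials)
    return TrialEnsemble(x, label="X"), TrialEnsemble(y, label="Y")


@pytest.fixture(scope="session")
def lag1_pair():
    return make_lag1_pair(a=0.5, b=0.4, c=0.6, n_trials=4096, n_time=20, seed=7)
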