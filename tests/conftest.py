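import numpy as np
import pytest

from twinmod.simulate import SimulationConfig, StratumSpec, simulate_cohorts, simulate_group
from twinmod.preprocess import TwinPreprocessor


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def small_dataset():
    """~600 pairs, one measured age — fast fixture for record-level tests."""
    cfg = SimulationConfig.from_total(600, seed=11, age_grid=[10])
    return simulate_cohorts(cfg)


@pytest.fixture(scope="session")
def small_pairs(small_dataset):
    return TwinPreprocessor().fit(small_dataset).pairs_


@pytest.fixture(scope="session")
def balanced_group_data():
    """Latent pair deviations for all five zygosity-sex groups, one stratum."""
    rng = np.random.default_rng(77)
    spec = StratumSpec("mid", A_m=48, C_m=6, E_m=6, A_f=40, C_f=5, E_f=5, r_os=0.4)
    return spec, {g: simulate_group(spec, g, 1500, rng) for g in ("MZM", "MZF", "DZM", "DZF", "OSDZ")}


def exact_moment_pairs(target_cov, target_mean, n, rng):
    """Gaussian draws transformed to have *exactly* the requested sample mean
    and (1/n-normalized) sample covariance — lets tests pin sample moments
    instead of hunting for seeds."""
    x = rng.standard_normal((n, 2))
    x -= x.mean(axis=0)
    s = (x.T @ x) / n
    l_s = np.linalg.cholesky(s)
    l_t = np.linalg.cholesky(np.asarray(target_cov, dtype=float))
    y = x @ np.linalg.inv(l_s).T @ l_t.T
    return y + np.asarray(target_mean, dtype=float)
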