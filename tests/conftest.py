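"""Shared fixtures: small synthetic movies and FRAP curves with known truth."""

import numpy as np
import pytest

from fa_relax.frap_model import ExchangeParameters, simulate_recovery
from fa_relax.synthetic_data import MovieConfig, generate_movie


@pytest.fixture(scope="session")
def exchange_params() -> ExchangeParameters:
    return ExchangeParameters(d_c=1.2, k_on=0.01, k_off=0.005, k_bleach=2.2,
                              n_fa=1000.0, n_c=500.0)


@pytest.fixture(scope="session")
def frap_times() -> np.ndarray:
    return np.concatenate([[-3.0, -2.0, -1.0], np.linspace(0.0, 900.0, 200)])


@pytest.fixture(scope="session")
def noiseless_curve(exchange_params, frap_times):
    return simulate_recovery(exchange_params, frap_times)


@pytest.fixture(scope="session")
def default_movie():
    """Default noisy mid-group movie (3-min frames, drug at frame 5)."""
    return generate_movie(MovieConfig(seed=21))


@pytest.fixture(scope="session")
def clean_movie():
    """Noise-free, bleach-free movie for exact recovery checks."""
    cfg = MovieConfig(seed=8, shot_noise=False, read_noise_sd=0.0,
                      photobleach_tau_min=np.inf, n_peripheral=6, n_central=4)
    return generate_movie(cfg)
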