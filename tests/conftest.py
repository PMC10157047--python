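import numpy as np
import pandas as pd
import pytest

from erpsel.erp import ErpParams, extract_features
from erpsel.essearch import PredictorMatrix
from erpsel.synth import GenerativeConfig, simulate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_8x5(rng):
    """Small predictor matrix: 8 rows, 5 candidate variables."""
    X = rng.standard_normal((8, 5))
    y = X @ np.array([1.5, -2.0, 0.0, 0.5, 0.0]) + rng.standard_normal(8)
    return PredictorMatrix(y=y, X=X, names=[f"x{j}" for j in range(5)])


@pytest.fixture
def toy_10x8(rng):
    X = rng.standard_normal((10, 8))
    y = X[:, 0] - 0.5 * X[:, 3] + rng.standard_normal(10)
    return PredictorMatrix(y=y, X=X, names=[f"x{j}" for j in range(8)])


def small_config(**overrides):
    """Reduced-size generative config for fast pipeline tests."""
    defaults = dict(n_participants=6, n_sets=2, noise_sd=6.0)
    defaults.update(overrides)
    return GenerativeConfig(**defaults)


def small_erp_params(**overrides):
    defaults = dict(min_trials=10)
    defaults.update(overrides)
    return ErpParams(**defaults)


@pytest.fixture(scope="session")
def small_extraction():
    """One small synthetic dataset pushed through the extraction pipeline."""
    config = small_config(n_participants=12)
    recordings, participants = simulate_dataset(config, seed=7)
    extraction = extract_features(recordings, participants, small_erp_params())
    return config, recordings, participants, extraction
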