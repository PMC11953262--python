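"""Shared fixtures: all data is generated programmatically at test time."""

import numpy as np
import pytest

import spectracal as sc

# coarse 5-nm grid keeps ANN/FA tests fast (31 channels instead of 151)
COARSE_GRID = sc.WavelengthGrid(200.0, 350.0, 5.0)
FULL_GRID = sc.WavelengthGrid(200.0, 400.0, 1.0)


@pytest.fixture(scope="session")
def full_grid():
    return FULL_GRID


@pytest.fixture(scope="session")
def coarse_grid():
    return COARSE_GRID


@pytest.fixture(scope="session")
def profiles_full():
    return sc.default_ternary_library(FULL_GRID)


@pytest.fixture(scope="session")
def profiles_coarse():
    return sc.default_ternary_library(COARSE_GRID)


@pytest.fixture(scope="session")
def cal_design():
    return sc.five_level_partial_factorial(sc.DesignSpec())


@pytest.fixture(scope="session")
def val_design():
    return sc.central_composite(sc.DesignSpec(kind="central_composite"))


@pytest.fixture(scope="session")
def noiseless_cal(cal_design, profiles_coarse):
    """25-run noiseless calibration set on the coarse grid."""
    return sc.simulate_dataset(cal_design, profiles_coarse, sc.NOISE_NONE,
                               seed=3, grid=COARSE_GRID)


@pytest.fixture(scope="session")
def noisy_cal_full(cal_design, profiles_full):
    """25-run calibration set at the default noise level, 200-400 nm."""
    return sc.simulate_dataset(cal_design, profiles_full, sc.NOISE_DEFAULT,
                               seed=11, grid=FULL_GRID)


@pytest.fixture(scope="session")
def noisy_val_full(val_design, profiles_full):
    """20-run CCD validation set at the default noise level, 200-400 nm."""
    return sc.simulate_dataset(val_design, profiles_full, sc.NOISE_DEFAULT,
                               seed=12, grid=FULL_GRID)


@pytest.fixture(scope="session")
def fast_ann_config():
    return sc.AnnConfig(n_hidden=2, n_restarts=1, max_epochs=200, seed=5)
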