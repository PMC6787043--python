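"""Shared fixtures: small synthetic cohorts and helpers used across tests."""

import warnings

import numpy as np
import pytest

from ramanmargin.bands import extract_band_features, reference_bands
from ramanmargin.preprocess import preprocess_cohort
from ramanmargin.synthetic import (
    BandComponent,
    default_config,
    simulate_cohort,
)


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    """Baseline non-convergence and rank-deficiency warnings are contract
    behaviour on tiny fixtures; keep test output readable."""
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*did not converge.*")
        warnings.filterwarnings("ignore", message=".*rank-deficient.*")
        yield


def neutralize(cfg):
    """Copy of a generator config with zero class effect on every band."""
    bands = [
        BandComponent(b.center, b.width, b.healthy_amp, b.healthy_amp,
                      b.assignment, b.pool)
        for b in cfg.bands
    ]
    return cfg.with_(bands=bands)


@pytest.fixture(scope="session")
def small_cohort_1064():
    """10 healthy + 10 tumor preprocessed 1064 nm spectra (seed 0)."""
    cfg = default_config(1064, seed=0)
    return preprocess_cohort(simulate_cohort(10, 10, 0, cfg))


@pytest.fixture(scope="session")
def small_features_1064(small_cohort_1064):
    return extract_band_features(small_cohort_1064, reference_bands(1064))


def rng(seed=0):
    return np.random.default_rng(seed)
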