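"""Shared fixtures: photophysics presets and small simulated cohorts."""

import numpy as np
import pytest

from pprfret import (
    HMMPriors,
    PhotophysicsConfig,
    channel_noise_for_fret_sd,
    fit_hmm,
)
from pprfret.simulate import two_state_scheme


@pytest.fixture(scope="session", autouse=True)
def _warm_hmm_kernels():
    # trigger numba compilation once so per-test timings stay meaningful
    fit_hmm(np.r_[np.full(15, 0.4), np.full(15, 0.8)], HMMPriors(k_range=(1, 2), restarts=1), seed=0)


@pytest.fixture
def noiseless_phys():
    return PhotophysicsConfig(total_intensity=1000.0, crosstalk_g=0.0, noise_sd=0.0)


@pytest.fixture
def study_phys():
    """Conditions of the simulated study: I = 1000, g = 0.07, FRET noise 0.08,
    per-dye bleach lifetime 240 s (molecule imaging lifetime ~120 s)."""
    return PhotophysicsConfig(
        total_intensity=1000.0,
        crosstalk_g=0.07,
        noise_sd=channel_noise_for_fret_sd(0.08, 1000.0),
        donor_bleach_mean=240.0,
        acceptor_bleach_mean=240.0,
    )


@pytest.fixture
def switching_scheme():
    return two_state_scheme(fret_unbound=0.4, fret_bound=0.8, k_on=0.1, k_off=0.1)


@pytest.fixture
def fast_priors():
    """Reduced restart count for unit tests (full defaults exercised in the
    acceptance suite)."""
    return HMMPriors(restarts=2, k_range=(1, 2, 3))
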