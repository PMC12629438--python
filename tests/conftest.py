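"""Shared fixtures: small simulated corpora and synthetic target profiles."""

from __future__ import annotations

import numpy as np
import pytest

from gazedegrade.io import PercentileProfile, percentile_profile_from_values
from gazedegrade.sim import (
    CorpusSpec,
    SimQualitySpec,
    simulate_corpus,
    simulate_recording,
    simulate_stimulus,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_corpus():
    """Ten simulated 1000 Hz source files with lognormal fixation noise."""
    return simulate_corpus(CorpusSpec(n_files=10, seed=101))


@pytest.fixture(scope="session")
def noiseless_pair():
    """One noiseless recording (planted 200 ms latency) and its stimulus."""
    rng = np.random.default_rng(7)
    stim = simulate_stimulus(10, (1000.0, 1500.0), 15.0, rng)
    rec = simulate_recording(
        stim, SimQualitySpec(fixation_noise_sd=0.0, latency_ms=200.0), rng
    )
    return rec, stim


def synthetic_target_profiles(
    seed: int = 7,
    n: int = 300,
    mad_c_median: float = 0.4,
    mad_c_sigma_log: float = 0.3,
    theta_scale: float = 0.6,
    temporal_sd_ms: float = 0.5,
) -> dict[str, PercentileProfile]:
    """Percentile profiles emulating a VR-headset-grade target device.

    Combined spatial precision is right-skewed (lognormal), per-channel
    accuracy is folded-normal, and temporal precision concentrates near
    ``temporal_sd_ms`` — the regime of a 250 Hz headset tracker with a
    slightly unstable sample clock.
    """
    rng = np.random.default_rng(seed)
    return {
        "mad_c": percentile_profile_from_values(
            rng.lognormal(np.log(mad_c_median), mad_c_sigma_log, n), "mad_c"
        ),
        "theta_h": percentile_profile_from_values(
            np.abs(rng.normal(0.0, theta_scale, n)), "theta_h"
        ),
        "theta_v": percentile_profile_from_values(
            np.abs(rng.normal(0.0, theta_scale, n)), "theta_v"
        ),
        "temporal_precision_ms": percentile_profile_from_values(
            rng.normal(temporal_sd_ms, 0.02, n), "temporal_precision_ms"
        ),
    }
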