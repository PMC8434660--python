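"""Shared fixtures: synthetic trials analyzed once per session."""

import numpy as np
import pytest

from gaitpath import SyntheticGaitSpec, analyze_sequence, simulate_gait
from gaitpath.synthetic import good_pattern, impaired_pattern


@pytest.fixture(scope="session")
def default_trial():
    """One default-condition synthetic walk: (sequence, ground truth, result)."""
    spec = SyntheticGaitSpec(seed=11)
    seq, gt = simulate_gait(spec)
    return seq, gt, analyze_sequence(seq)


@pytest.fixture(scope="session")
def good_trial():
    spec = good_pattern(seed=21)
    seq, gt = simulate_gait(spec)
    return seq, gt, analyze_sequence(seq)


@pytest.fixture(scope="session")
def impaired_trial():
    spec = impaired_pattern(seed=31)
    seq, gt = simulate_gait(spec)
    return seq, gt, analyze_sequence(seq)


@pytest.fixture(scope="session")
def noiseless_walk():
    """A clean (no noise, no jitter) walk for exactness-sensitive checks."""
    spec = SyntheticGaitSpec(seed=41, noise_sd_m=0.0, jitter_sd_hz=0.0)
    seq, gt = simulate_gait(spec)
    return seq, gt, analyze_sequence(seq)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
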