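"""Shared fixtures: deterministic RNGs and small synthetic datasets."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from hmaze.cohort import ParticipantProfile, simulate_session
from hmaze.strategies import StrategyParams

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tmaze_session():
    """3000 T-maze trials simulated at w=0.15, lapse=0.05."""
    profile = ParticipantProfile(task="tmaze", w=0.15, lapse=0.05,
                                 n_trials=3000, seed=101)
    return simulate_session(profile)


@pytest.fixture(scope="session")
def counterfactual_session():
    """One H-maze session from a counterfactual decision maker."""
    profile = ParticipantProfile(
        strategy="counterfactual", params=StrategyParams(0.0, 0.3, 0.0),
        w=0.15, task="hmaze", n_trials=540, seed=202)
    return simulate_session(profile)


@pytest.fixture(scope="session")
def optimal_session():
    profile = ParticipantProfile(strategy="optimal", w=0.15, task="hmaze",
                                 n_trials=540, seed=203)
    return simulate_session(profile)
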