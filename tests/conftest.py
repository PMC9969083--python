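"""Shared fixtures: canonical athlete profiles and simulated recordings.

Profiles are built from the sex-specific cohort means so tests exercise the
same physiology the cohort generator emulates; expensive simulations are
session-scoped.
"""

import numpy as np
import pytest

from cpetkit import AthleteProfile, DEFAULT_PROTOCOL, simulate_rest, simulate_test
from cpetkit.simulate import COHORT_DISTRIBUTIONS, _SHARED


def make_profile(sex: str = "male", noise_cv: float = 0.0, **overrides) -> AthleteProfile:
    """Athlete at the sex-specific cohort means (deterministic, no sampling)."""
    params = {k: m for k, (m, _) in COHORT_DISTRIBUTIONS[sex].items()}
    shared = {k: m for k, (m, _) in _SHARED.items()}
    eq_start = params["cop_value"] + shared.pop("eq_start_offset")
    params.update(shared)
    params.update(sex=sex, eq_start=eq_start, noise_cv=noise_cv,
                  athlete_id=f"{sex[0].upper()}00")
    params.update(overrides)
    return AthleteProfile(**params)


@pytest.fixture(scope="session")
def male_profile():
    return make_profile("male")


@pytest.fixture(scope="session")
def female_profile():
    return make_profile("female")


@pytest.fixture(scope="session")
def noiseless_test(male_profile):
    """One noiseless male ramp test plus its ground truth."""
    return simulate_test(male_profile, DEFAULT_PROTOCOL, seed=42)


@pytest.fixture(scope="session")
def noisy_test():
    """One 5%-CV male ramp test plus its ground truth."""
    profile = make_profile("male", noise_cv=0.05)
    return simulate_test(profile, DEFAULT_PROTOCOL, seed=42)


@pytest.fixture(scope="session")
def noiseless_rest(male_profile):
    return simulate_rest(male_profile, duration=2400.0, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
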