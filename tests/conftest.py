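"""Shared fixtures: shrunken system profiles for fast unit tests."""

from dataclasses import replace

import numpy as np
import pytest

from perceptmeg.profiles import SystemProfile, make_profile


def shrink(profile: SystemProfile, n_channels: int) -> SystemProfile:
    """Profile with only the first ``n_channels`` channels (fast tests)."""
    return replace(profile, channels=profile.channels[:n_channels])


@pytest.fixture(scope="session")
def ctf_small() -> SystemProfile:
    return shrink(make_profile("ctf"), 24)


@pytest.fixture(scope="session")
def megin_small() -> SystemProfile:
    # 8 sensor triplets: 8 magnetometers + 16 planar gradiometers
    return shrink(make_profile("megin"), 24)


@pytest.fixture(scope="session")
def opm_small() -> SystemProfile:
    return shrink(make_profile("opm"), 16)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
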